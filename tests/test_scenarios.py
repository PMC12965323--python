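"""Scenario accounting: REF bookkeeping, expansion, water limits, summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from multicrop import (
    RunConfig,
    classify_suitability,
    generate_world,
    percent_increase,
    run_pipeline,
    share_pct,
    summarize,
)
from multicrop.config import EfficiencyTable
from multicrop.errors import MulticropError
from multicrop.scenarios import SYSTEM_COLS, build_ref
from multicrop.water import fit_offseason_regressions, irrigation_demand_per_ha
from multicrop.yields import build_yield_table

from conftest import make_world


def _suitable_one_cell_world(irr_phys=100.0, ci=1.5):
    gpp = np.full((1, 12), 150.0)
    season = np.zeros((1, 1, 12), dtype=bool)
    season[:, :, :6] = True
    physical = np.zeros((1, 1, 2))
    physical[0, 0, 1] = irr_phys
    harvested = physical * ci
    return make_world(
        lat=[10.0],
        lon=[0.0],
        downstream=[-1],
        basin_id=[0],
        runoff=[100.0],
        gpp_rf=gpp,
        gpp_irr=gpp,
        season=season,
        y_main=np.full((1, 1, 2), 4.0),
        physical=physical,
        harvested=harvested,
        et_rf=np.full((1, 1), 300.0),
        et_irr=np.full((1, 1), 500.0),
    )


def test_ref_hand_example_mc_area_and_production():
    # one cell, 100 ha irrigated, CI=1.5, y_main=4, y_off forced to 2:
    # MC area 50 ha, production 50*4 + 50*(4+2) = 500 t
    world = _suitable_one_cell_world()
    suit = classify_suitability(world.gpp)
    ytable = build_yield_table(world, suit)
    ytable["y_off"] = xr.full_like(ytable["y_off"], 2.0)
    ytable["y_annual_mc"] = ytable["y_main"] + ytable["y_off"]
    regs = fit_offseason_regressions(world) if False else None
    # demand values are irrelevant to the area/production bookkeeping here
    from multicrop.water import IrrigationDemand

    zero = xr.zeros_like(world.crops["main_yield"].sel(regime="irrigated", drop=True))
    demand = IrrigationDemand(zero, zero, np.ones(1), np.ones(1))
    ref = build_ref(world, suit, ytable, demand)
    assert ref.areas.loc[0, "irrigated_mc"] == pytest.approx(50.0)
    assert ref.areas.loc[0, "irrigated_single"] == pytest.approx(50.0)
    total_prod = ref.production.loc[0, ["irrigated_single", "irrigated_mc"]].sum()
    assert total_prod == pytest.approx(50 * 4 + 50 * 6)


def test_ref_without_multiple_cropping_is_single_only(world_small):
    flat = world_small.crops.copy()
    flat["harvested_area"] = world_small.crops["physical_area"].copy()
    w = dataclasses.replace(world_small, crops=flat)
    out = run_pipeline(w)
    ref = out["REF"]
    assert ref.areas[["rainfed_mc", "irrigated_mc"]].to_numpy().sum() == 0.0
    # production equals sum of physical area x calibrated main yield
    y = out["yields"]["y_main"]
    a = w.crops["physical_area"]
    expected = float((a * y).sum())
    got = ref.production[list(SYSTEM_COLS)].to_numpy().sum()
    assert got == pytest.approx(expected, rel=1e-9)


def test_ref_matches_per_cell_loop_oracle(world_small, pipeline_small):
    ref = pipeline_small["REF"]
    ytable = pipeline_small["yields"]
    phys = world_small.crops["physical_area"]
    harv = world_small.crops["harvested_area"]
    for cell in world_small.cell_ids[:15]:
        prod = dict.fromkeys(SYSTEM_COLS, 0.0)
        for crop in world_small.crop_names:
            for ri, regime in enumerate(("rainfed", "irrigated")):
                a = float(phys.sel(cell=cell, crop=crop, regime=regime))
                h = float(harv.sel(cell=cell, crop=crop, regime=regime))
                share = min(h / a - 1.0, 1.0) if a > 0 else 0.0
                y1 = float(
                    ytable["y_annual_single"].sel(cell=cell, crop=crop, regime=regime)
                )
                y2 = float(
                    ytable["y_annual_mc"].sel(cell=cell, crop=crop, regime=regime)
                )
                prod[f"{regime}_single"] += (1 - share) * a * y1
                prod[f"{regime}_mc"] += share * a * y2
        for col in SYSTEM_COLS:
            assert ref.production.loc[cell, col] == pytest.approx(prod[col], rel=1e-9)


def test_nwl_expands_everything_suitable(world_small, pipeline_small):
    nwl = pipeline_small["NWL"]
    suit = pipeline_small["suitable"]
    s_rf = suit.sel(regime="rainfed").values
    s_ir = suit.sel(regime="irrigated").values
    phys = world_small.crops["physical_area"]
    a_rf = phys.sel(regime="rainfed").sum(dim="crop").values
    a_ir = phys.sel(regime="irrigated").sum(dim="crop").values
    # rainfed-suitable cells: all rainfed area multiple cropped
    got = nwl.areas["rainfed_mc"].to_numpy()
    assert np.allclose(got[s_rf], a_rf[s_rf], rtol=1e-12)
    # irrigation-enabled cells: all previously rainfed single area converted
    enabled = s_ir & ~s_rf
    assert np.allclose(
        nwl.enabled_mc_area.to_numpy()[enabled],
        (a_rf - nwl.areas["rainfed_mc"].to_numpy())[enabled],
        rtol=1e-9,
        atol=1e-9,
    )
    # irrigated-suitable cells: all irrigated area multiple cropped
    on_irr = nwl.areas["irrigated_mc"].to_numpy() - nwl.enabled_mc_area.to_numpy()
    assert np.allclose(on_irr[s_ir], a_ir[s_ir], rtol=1e-9, atol=1e-9)


def test_nwl_equals_ref_when_nothing_is_suitable(world_small):
    cfg = RunConfig(min_growing_months=12, gpp_threshold=1e6)
    out = run_pipeline(world_small, cfg)
    pd.testing.assert_frame_equal(out["NWL"].areas, out["REF"].areas)
    pd.testing.assert_frame_equal(out["NWL"].production, out["REF"].production)


def test_per_stratum_nwl_areas_match_generator_bookkeeping():
    w = generate_world(17, 60, 5)
    out = run_pipeline(w)
    nwl = out["NWL"]
    stratum = w.grid["stratum"].to_numpy()
    active_rf = w.crops["physical_area"].sel(regime="rainfed").sum(dim="crop").values
    # every rainfed ha in the rainfed_suitable stratum is multiple cropped
    mask = stratum == "rainfed_suitable"
    assert np.allclose(nwl.areas["rainfed_mc"].to_numpy()[mask], active_rf[mask])
    # irrigation-enabled conversion happens exactly in the irrigated_only stratum
    enabled_cells = nwl.enabled_mc_area.to_numpy() > 0
    assert set(stratum[enabled_cells]) <= {"irrigated_only"}


def test_pot_equals_nwl_with_unlimited_runoff(world_small):
    flooded = dataclasses.replace(world_small, runoff=world_small.runoff * 1e6 + 1e3)
    out = run_pipeline(flooded)
    pd.testing.assert_frame_equal(out["POT"].areas, out["NWL"].areas, atol=0, rtol=0)
    pd.testing.assert_frame_equal(
        out["POT"].production, out["NWL"].production, atol=0, rtol=0
    )
    assert out["POT"].water["groundwater_km3"].sum() == 0.0


def test_pot_with_zero_runoff_books_committed_to_groundwater(world_small):
    dry = dataclasses.replace(
        world_small,
        runoff=np.zeros(world_small.n_cells),
        nonag=world_small.nonag * 0.0,
    )
    out = run_pipeline(dry)
    pot = out["POT"]
    # no irrigated expansion at all: irrigated areas stay at REF, nothing
    # is converted, while rainfed MC expansion (needing no water) proceeds
    for col in ("irrigated_single", "irrigated_mc"):
        assert np.allclose(
            pot.areas[col].to_numpy(), out["REF"].areas[col].to_numpy(), atol=1e-12
        )
    assert pot.enabled_mc_area.sum() == 0.0
    assert np.allclose(
        pot.areas["rainfed_mc"].to_numpy(),
        out["NWL"].areas["rainfed_mc"].to_numpy(),
        atol=1e-9,
    )
    # committed REF withdrawal demand fully booked as groundwater
    committed = out["REF"].water["withdrawal_km3"].to_numpy()
    assert np.allclose(pot.water["groundwater_km3"].to_numpy(), committed, atol=1e-12)


def test_scenario_orderings_and_conservation(pipeline_small):
    ref, pot, nwl = (
        pipeline_small["REF"],
        pipeline_small["POT"],
        pipeline_small["NWL"],
    )
    for col in ("rainfed_mc", "irrigated_mc"):
        assert (ref.areas[col] <= pot.areas[col] + 1e-9).all()
        assert (pot.areas[col] <= nwl.areas[col] + 1e-9).all()
    for r in (ref, pot, nwl):
        total = r.areas.sum(axis=1)
        assert np.allclose(total, ref.areas.sum(axis=1), rtol=1e-9)
        assert (
            r.water["withdrawal_km3"] >= r.water["consumption_km3"] - 1e-12
        ).all()
    p_ref = ref.production[list(SYSTEM_COLS)].sum(axis=1)
    p_pot = pot.production[list(SYSTEM_COLS)].sum(axis=1)
    p_nwl = nwl.production[list(SYSTEM_COLS)].sum(axis=1)
    assert (p_ref <= p_pot + 1e-6).all()
    assert (p_pot <= p_nwl + 1e-6).all()
    # water ordering: NWL demand >= POT allocation >= REF demand
    assert nwl.water["withdrawal_km3"].sum() >= pot.water["withdrawal_km3"].sum() - 1e-9
    assert pot.water["withdrawal_km3"].sum() >= ref.water["withdrawal_km3"].sum() - 1e-9


def test_average_mc_yield_at_least_single(pipeline_small):
    tables = summarize(
        [pipeline_small["REF"], pipeline_small["POT"], pipeline_small["NWL"]]
    )
    g = tables["global"]
    for scen in g.index:
        for regime in ("rainfed", "irrigated"):
            y_mc = g.loc[scen, f"yield_{regime}_mc_t_ha"]
            y_s = g.loc[scen, f"yield_{regime}_single_t_ha"]
            if np.isfinite(y_mc) and np.isfinite(y_s):
                assert y_mc >= y_s - 1e-9


def test_summarize_share_arithmetic_and_errors():
    assert share_pct(260.0, 1236.0) == pytest.approx(21.0, abs=0.1)
    assert np.isnan(share_pct(1.0, 0.0))  # undefined, not 0
    assert np.isnan(percent_increase(0.0, 5.0))
    with pytest.raises(MulticropError):
        summarize([])


def test_end_to_end_determinism_byte_identical(tmp_path, world_small):
    from multicrop import write_summary

    for sub in ("a", "b"):
        out = run_pipeline(world_small)
        tables = summarize([out["REF"], out["NWL"], out["POT"]])
        write_summary(tables, tmp_path / sub)
    for fn in ("summary_global.csv", "summary_cells.csv", "summary_global.json"):
        assert (tmp_path / "a" / fn).read_bytes() == (tmp_path / "b" / fn).read_bytes()
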