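"""Scenario assembly: REF (reference state), NWL (maximum multiple-cropping
expansion with no water limitation) and POT (expansion under local water
availability constraints).

All scenarios share the same physical cropland extent; they differ only
in how the active (non-fallow) area is managed:

* **REF** keeps the 2010-style management: multiple-cropped shares come
  from cropping intensity (min(CI - 1, 1)) per cell-crop-regime, and
  irrigation demand covers the existing irrigated areas under those
  multiple-cropping patterns.
* **NWL** expands every suitable rainfed cell-crop to full rainfed
  multiple cropping, every irrigated-suitable irrigated cell-crop to
  full irrigated multiple cropping, and converts rainfed areas to
  irrigated multiple cropping where irrigation enables a second season
  that rainfed conditions cannot support (rainfed-unsuitable but
  irrigated-suitable; the "irrigation-enabled" class).  Water demand is
  reported, not constrained.
* **POT** is NWL with the irrigated expansion scaled per cell by the
  fulfilled fraction of an upstream-downstream water allocation:
  non-agricultural demand first, committed (REF) irrigation second
  (shortfalls booked to non-renewable groundwater), expansion last,
  ranked by the yield gain irrigation brings.  Rainfed expansion needs
  no water and proceeds as in NWL.

NWL is computed by the same code path as POT with fulfilled fraction
identically 1, so the unlimited-water limit of POT reproduces NWL
exactly.  Fallow land never participates in expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .allocation import (
    AllocationRequest,
    RiverNetwork,
    allocate,
    rank_expansion_cells,
    sort_requests,
)
from .config import MM_HA_TO_KM3, RunConfig
from .errors import MulticropError
from .suitability import SuitabilityParams, classify_suitability
from .water import IrrigationDemand, fit_offseason_regressions, irrigation_demand_per_ha
from .world import World
from .yields import YieldParams, build_yield_table, calibrate_yields, ci_to_mc_share

SYSTEM_COLS = ("rainfed_single", "rainfed_mc", "irrigated_single", "irrigated_mc")


@dataclass
class ScenarioResult:
    """Cell-level accounting for one scenario.

    areas: ha per cell by management system (+ fallow).
    production: t DM per cell by management system.
    water: km^3/yr per cell — irrigation withdrawal/consumption (committed
    plus expansion), non-agricultural demand, and non-renewable groundwater.
    enabled_mc_area: ha per cell of irrigation-enabled multiple cropping
    (previously rainfed area irrigated in the scenario).
    """

    name: str
    areas: pd.DataFrame
    production: pd.DataFrame
    water: pd.DataFrame
    enabled_mc_area: pd.Series
    expansion_fraction: np.ndarray | None = None


def ref_mc_share(world: World) -> xr.DataArray:
    """Multiple-cropped share per (cell, crop, regime) from cropping intensity."""
    phys = world.crops["physical_area"]
    harv = world.crops["harvested_area"]
    share = ci_to_mc_share(phys.values, harv.values)
    return xr.DataArray(share, coords=phys.coords, dims=phys.dims)


def _water_frame(world, cons_field, eff_wd, eff_cons, groundwater=None):
    wd = cons_field * eff_wd
    cons = cons_field * eff_cons
    return pd.DataFrame(
        {
            "withdrawal_km3": wd,
            "consumption_km3": cons,
            "nonag_withdrawal_km3": world.nonag["withdrawal_km3"].to_numpy(),
            "nonag_consumption_km3": world.nonag["consumption_km3"].to_numpy(),
            "groundwater_km3": np.zeros(world.n_cells) if groundwater is None else groundwater,
        },
        index=world.cell_ids,
    )


def _result(world, name, a_rf_s, a_rf_mc, a_ir_s, a_ir_mc, enabled, ytable, water, frac=None):
    """Assemble a ScenarioResult from per-(cell,crop) area components."""
    y_single = ytable["y_annual_single"]
    y_mc = ytable["y_annual_mc"]
    prod = {
        "rainfed_single": (a_rf_s * y_single.sel(regime="rainfed")).sum(dim="crop"),
        "rainfed_mc": (a_rf_mc * y_mc.sel(regime="rainfed")).sum(dim="crop"),
        "irrigated_single": (a_ir_s * y_single.sel(regime="irrigated")).sum(dim="crop"),
        "irrigated_mc": (a_ir_mc * y_mc.sel(regime="irrigated")).sum(dim="crop"),
    }
    areas = pd.DataFrame(
        {
            "rainfed_single": a_rf_s.sum(dim="crop").values,
            "rainfed_mc": a_rf_mc.sum(dim="crop").values,
            "irrigated_single": a_ir_s.sum(dim="crop").values,
            "irrigated_mc": a_ir_mc.sum(dim="crop").values,
            "fallow": world.fallow_area,
        },
        index=world.cell_ids,
    )
    production = pd.DataFrame(
        {k: v.values for k, v in prod.items()}, index=world.cell_ids
    )
    return ScenarioResult(
        name=name,
        areas=areas,
        production=production,
        water=water,
        enabled_mc_area=pd.Series(enabled.sum(dim="crop").values, index=world.cell_ids),
        expansion_fraction=frac,
    )


def _committed_consumption(world, demand: IrrigationDemand, s_ir) -> xr.DataArray:
    """REF field consumption km^3/yr per cell: main on all irrigated area,
    off-season on the multiple-cropped part."""
    a_ir = world.crops["physical_area"].sel(regime="irrigated", drop=True)
    per_crop = (demand.main_mm * a_ir + demand.off_mm * s_ir * a_ir) * MM_HA_TO_KM3
    return per_crop.sum(dim="crop")


def build_ref(
    world: World,
    suitable: xr.DataArray,
    ytable: xr.Dataset,
    demand: IrrigationDemand,
) -> ScenarioResult:
    """Reference state: management as given by the crop-area data."""
    share = ref_mc_share(world)
    phys = world.crops["physical_area"]
    a_rf = phys.sel(regime="rainfed", drop=True)
    a_ir = phys.sel(regime="irrigated", drop=True)
    s_rf = share.sel(regime="rainfed", drop=True)
    s_ir = share.sel(regime="irrigated", drop=True)
    cons_field = _committed_consumption(world, demand, s_ir).values
    water = _water_frame(world, cons_field, demand.wd_factor, demand.cons_factor)
    return _result(
        world,
        "REF",
        (1 - s_rf) * a_rf,
        s_rf * a_rf,
        (1 - s_ir) * a_ir,
        s_ir * a_ir,
        xr.zeros_like(a_rf),
        ytable,
        water,
    )


def _expansion_components(world, suitable, demand):
    """Shared NWL/POT pieces; returns area blocks and per-cell expansion demand."""
    share = ref_mc_share(world)
    phys = world.crops["physical_area"]
    a_rf = phys.sel(regime="rainfed", drop=True)
    a_ir = phys.sel(regime="irrigated", drop=True)
    s_rf = share.sel(regime="rainfed", drop=True)
    s_ir = share.sel(regime="irrigated", drop=True)
    suit_rf = suitable.sel(regime="rainfed", drop=True)
    suit_ir = suitable.sel(regime="irrigated", drop=True)
    enabled_cells = suit_ir & ~suit_rf
    # rainfed area convertible to irrigated MC (single-cropped part only)
    convertible = xr.where(enabled_cells, (1 - s_rf) * a_rf, 0.0)
    # irrigated area that can gain an extra season
    expandable_ir = xr.where(suit_ir, (1 - s_ir) * a_ir, 0.0)
    # expansion field-consumption demand per cell (km^3/yr)
    exp_cons = (
        (demand.off_mm * expandable_ir + (demand.main_mm + demand.off_mm) * convertible)
        * MM_HA_TO_KM3
    ).sum(dim="crop")
    return share, a_rf, a_ir, s_rf, s_ir, suit_rf, suit_ir, convertible, expandable_ir, exp_cons


def _build_expansion(world, suitable, ytable, demand, name, fraction, water, s_ir_committed=None):
    """Area/production bookkeeping for an expansion scenario at fulfilled
    fraction *fraction* (per cell, 1 = unconstrained = NWL)."""
    (share, a_rf, a_ir, s_rf, s_ir, suit_rf, suit_ir,
     convertible, expandable_ir, _) = _expansion_components(world, suitable, demand)
    f = xr.DataArray(fraction, coords={"cell": a_rf.coords["cell"]}, dims=("cell",))

    converted = f * convertible
    a_rf_mc = xr.where(suit_rf, a_rf, s_rf * a_rf)
    a_rf_s = xr.where(suit_rf, 0.0, a_rf - s_rf * a_rf - converted)
    a_ir_mc = s_ir * a_ir + f * expandable_ir + converted
    a_ir_s = a_ir - s_ir * a_ir - f * expandable_ir
    return _result(
        world, name, a_rf_s, a_rf_mc, a_ir_s, a_ir_mc, converted, ytable, water,
        frac=np.asarray(fraction, dtype=float),
    )


def build_nwl(
    world: World,
    suitable: xr.DataArray,
    ytable: xr.Dataset,
    demand: IrrigationDemand,
) -> ScenarioResult:
    """No-water-limitation expansion: POT's code path with fraction 1."""
    share = ref_mc_share(world)
    s_ir = share.sel(regime="irrigated", drop=True)
    *_, exp_cons = _expansion_components(world, suitable, demand)
    cons_field = _committed_consumption(world, demand, s_ir).values + exp_cons.values
    water = _water_frame(world, cons_field, demand.wd_factor, demand.cons_factor)
    return _build_expansion(
        world, suitable, ytable, demand, "NWL", np.ones(world.n_cells), water
    )


def build_pot(
    world: World,
    suitable: xr.DataArray,
    ytable: xr.Dataset,
    demand: IrrigationDemand,
    radius_km: float = 100.0,
) -> tuple[ScenarioResult, "AllocationDetail"]:
    """Water-constrained expansion via priority allocation on the river network."""
    share = ref_mc_share(world)
    s_ir = share.sel(regime="irrigated", drop=True)
    *_, exp_cons = _expansion_components(world, suitable, demand)
    committed_field = _committed_consumption(world, demand, s_ir).values
    exp_field = exp_cons.values

    network = RiverNetwork.from_world(world)
    rank = rank_expansion_cells(world, ytable, share)
    requests = []
    nonag_w = world.nonag["withdrawal_km3"].to_numpy()
    nonag_c = world.nonag["consumption_km3"].to_numpy()
    for c in range(world.n_cells):
        if nonag_w[c] > 0:
            requests.append(
                AllocationRequest(c, "non_ag", nonag_w[c], nonag_c[c])
            )
        if committed_field[c] > 0:
            requests.append(
                AllocationRequest(
                    c,
                    "committed",
                    committed_field[c] * demand.wd_factor[c],
                    committed_field[c] * demand.cons_factor[c],
                )
            )
        if exp_field[c] > 0:
            requests.append(
                AllocationRequest(
                    c,
                    "expansion",
                    exp_field[c] * demand.wd_factor[c],
                    exp_field[c] * demand.cons_factor[c],
                    rank=rank[c],
                )
            )
    requests = sort_requests(requests, world.basin_id)
    result = allocate(requests, network, world.lat, world.lon, radius_km)

    fraction = np.ones(world.n_cells)
    for req, frac in zip(requests, result.fractions):
        if req.purpose == "expansion":
            fraction[req.cell] = frac

    cons_field = committed_field + fraction * exp_field
    water = _water_frame(
        world, cons_field, demand.wd_factor, demand.cons_factor, result.groundwater
    )
    scenario = _build_expansion(
        world, suitable, ytable, demand, "POT", fraction, water
    )
    detail = AllocationDetail(requests=requests, result=result)
    return scenario, detail


@dataclass
class AllocationDetail:
    requests: list
    result: object


def run_pipeline(world: World, config: RunConfig | None = None) -> dict:
    """End-to-end run: suitability -> yields (calibrated) -> water demand ->
    REF/NWL/POT.  Returns a dict with the scenario results and the
    intermediate products."""
    cfg = config or RunConfig()
    cfg.validate()
    sparams = SuitabilityParams(
        gpp_threshold=cfg.gpp_threshold,
        min_growing_months=cfg.min_growing_months,
        consecutive=cfg.consecutive_months,
    )
    yparams = YieldParams(
        offseason_dampening=cfg.offseason_dampening,
        calibration_cap=cfg.calibration_cap,
    )
    suitable = classify_suitability(world.gpp, sparams)
    ytable = build_yield_table(world, suitable, yparams)
    ytable, factors = calibrate_yields(ytable, world, world.reported_yield, yparams)
    regressions = fit_offseason_regressions(world)
    demand = irrigation_demand_per_ha(
        world, suitable, regressions, cfg.efficiency, cfg.offseason_dampening
    )
    ref = build_ref(world, suitable, ytable, demand)
    nwl = build_nwl(world, suitable, ytable, demand)
    pot, detail = build_pot(world, suitable, ytable, demand, cfg.radius_km)
    return {
        "REF": ref,
        "NWL": nwl,
        "POT": pot,
        "suitable": suitable,
        "yields": ytable,
        "calibration_factors": factors,
        "regressions": regressions,
        "demand": demand,
        "allocation": detail,
    }
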