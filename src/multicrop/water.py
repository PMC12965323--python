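"""Irrigation water requirements: consumptive demand and withdrawals.

Main-season consumptive irrigation water requirement (IWR) of a crop is
the ET difference between irrigated and rainfed conditions over the same
(irrigated) growing season, composed of transpiration, evaporation and
interception, clamped at zero.

Off-season crop IWR cannot be simulated directly (crops only grow in
their main season in the crop model), so it is predicted from grass:
an OLS regression of crop consumptive IWR on grass consumptive IWR over
the main season, fit per crop and irrigation system, is applied to the
grass consumptive IWR of the off-season months and dampened by the same
fallow factor used for yields.

Withdrawals exceed field consumption by field and conveyance losses per
irrigation system (surface, sprinkler, drip); a configurable share of
conveyance losses is itself consumptive (evaporates) and the rest
returns to the river.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .config import MM_HA_TO_KM3, SYSTEMS, EfficiencyTable
from .errors import MulticropError, RegressionError
from .world import World

log = logging.getLogger(__name__)


def main_season_consumptive_iwr(et_irr, et_rf):
    """max(ET_irrigated - ET_rainfed, 0), both over the irrigated season (mm)."""
    et_irr = np.asarray(et_irr, dtype=float)
    et_rf = np.asarray(et_rf, dtype=float)
    if (et_irr < 0).any() or (et_rf < 0).any():
        raise MulticropError("ET values must be >= 0")
    diff = et_irr - et_rf
    n_neg = int((diff < 0).sum())
    if n_neg:
        log.warning("%d negative ET differences clamped to 0", n_neg)
    out = np.maximum(diff, 0.0)
    return float(out) if out.ndim == 0 else out


def crop_main_iwc(world: World) -> xr.DataArray:
    """Crop main-season consumptive IWR (mm) per (cell, crop) from ET components."""
    et = (
        world.crops["transpiration"]
        + world.crops["evaporation"]
        + world.crops["interception"]
    )
    diff = et.sel(regime="irrigated") - et.sel(regime="rainfed")
    return diff.clip(min=0.0)


def grass_iwc(world: World, season_of: str = "main") -> xr.DataArray:
    """Grass consumptive IWR (mm) per (cell, crop) over main or off-season months.

    Defined analogously to crops: irrigated-minus-rainfed grass ET summed
    over the crop's irrigated-season months ('main') or their complement
    ('off'), clamped at zero month-wise via the GPP ordering guarantee.
    """
    if season_of not in ("main", "off"):
        raise MulticropError("season_of must be 'main' or 'off'")
    season = world.crops["season"].sel(regime="irrigated", drop=True)
    diff = world.grass_et.sel(regime="irrigated") - world.grass_et.sel(regime="rainfed")
    diff = diff.clip(min=0.0)
    mask = season if season_of == "main" else ~season
    out = diff.where(mask, 0.0).sum(dim="month")
    return out.transpose("cell", "crop")


@dataclass(frozen=True)
class RegressionEntry:
    """crop IWC ~ grass IWC over the main season, one crop-system combination."""

    crop: str
    system: str
    slope: float
    intercept: float
    r2: float
    n: int


def fit_offseason_regression(crop_iwc_v, grass_iwc_v, crop="", system="") -> RegressionEntry:
    """OLS of crop consumptive IWR on grass consumptive IWR across cells."""
    y = np.asarray(crop_iwc_v, dtype=float)
    x = np.asarray(grass_iwc_v, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RegressionError("crop and grass IWC vectors must be equal-length 1-D")
    if len(x) < 3:
        raise RegressionError(f"need >= 3 points to fit, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise RegressionError("zero variance in grass IWC; regression undefined")
    res = stats.linregress(x, y)
    return RegressionEntry(
        crop=crop,
        system=system,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def fit_offseason_regressions(world: World) -> pd.DataFrame:
    """Fit the crop-vs-grass IWC regression per crop x irrigation system.

    Pooled across cells; for each system only cells with a nonzero share
    of that system contribute, falling back to all cells when fewer than
    three use the system.  Returns a tidy frame
    (crop, system, slope, intercept, r2, n).
    """
    crop_v = crop_main_iwc(world)
    grass_v = grass_iwc(world, "main")
    rows = []
    for crop in world.crop_names:
        y_all = crop_v.sel(crop=crop).values
        x_all = grass_v.sel(crop=crop).values
        for system in SYSTEMS:
            use = world.system_shares[system].to_numpy() > 0
            if use.sum() < 3:
                use = np.ones_like(use)
            entry = fit_offseason_regression(
                y_all[use], x_all[use], crop=crop, system=system
            )
            rows.append(entry.__dict__)
    return pd.DataFrame(rows)


def offseason_consumptive_iwr(
    grass_iwc_off, entry: RegressionEntry, dampening: float = 0.25
):
    """Predicted off-season crop consumptive IWR (mm), clamped and dampened."""
    g = np.asarray(grass_iwc_off, dtype=float)
    if (g < 0).any():
        raise MulticropError("grass IWC must be >= 0")
    pred = np.maximum(entry.slope * g + entry.intercept, 0.0) * (1.0 - dampening)
    return float(pred) if pred.ndim == 0 else pred


def withdrawal_factors(
    system_shares: pd.DataFrame, eff: EfficiencyTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell linear factors converting field consumption to (withdrawal,
    total consumption including the consumptive share of conveyance losses).

    For system s with field efficiency fe and conveyance efficiency ce,
    one unit of field consumption requires a withdrawal of 1/(fe*ce);
    conveyance losses are (1-ce)/(fe*ce) of which a fixed share
    evaporates and adds to consumption.
    """
    eff.validate()
    shares = system_shares[list(SYSTEMS)].to_numpy()
    inv = np.array(
        [1.0 / (eff.field_efficiency[s] * eff.conveyance_efficiency[s]) for s in SYSTEMS]
    )
    loss = np.array(
        [
            (1.0 - eff.conveyance_efficiency[s])
            / (eff.field_efficiency[s] * eff.conveyance_efficiency[s])
            for s in SYSTEMS
        ]
    )
    wd = shares @ inv
    cons = 1.0 + eff.consumptive_loss_share * (shares @ loss)
    return wd, cons


def consumption_to_withdrawal(consumption, system_shares, eff: EfficiencyTable):
    """Convert field consumption (km^3) to (withdrawal, total consumption)."""
    wd_f, cons_f = withdrawal_factors(system_shares, eff)
    c = np.asarray(consumption, dtype=float)
    return c * wd_f, c * cons_f


@dataclass(frozen=True)
class IrrigationDemand:
    """Per-cell-crop irrigation water requirement building blocks.

    main_mm / off_mm are per-ha depths (mm); off_mm is already dampened
    and masked to zero where the cell is not irrigated-suitable.
    wd_factor / cons_factor are the per-cell consumption-to-withdrawal
    conversion factors.  Volumes follow as depth x area x 1e-8 km^3/mm-ha.
    """

    main_mm: xr.DataArray  # (cell, crop)
    off_mm: xr.DataArray  # (cell, crop)
    wd_factor: np.ndarray  # (cell,)
    cons_factor: np.ndarray  # (cell,)


def irrigation_demand_per_ha(
    world: World,
    suitable: xr.DataArray,
    regressions: pd.DataFrame,
    eff: EfficiencyTable,
    dampening: float = 0.25,
) -> IrrigationDemand:
    """Assemble per-ha main- and off-season consumptive IWR for every cell-crop."""
    main_mm = crop_main_iwc(world)
    grass_off = grass_iwc(world, "off")
    shares = world.system_shares
    reg = regressions.set_index(["crop", "system"])
    pred = xr.zeros_like(grass_off)
    for crop in world.crop_names:
        g = grass_off.sel(crop=crop).values
        total = np.zeros_like(g)
        for system in SYSTEMS:
            row = reg.loc[(crop, system)]
            p = np.maximum(row["slope"] * g + row["intercept"], 0.0)
            total += shares[system].to_numpy() * p
        pred.loc[{"crop": crop}] = total
    off_mm = pred * (1.0 - dampening)
    suit_irr = suitable.sel(regime="irrigated", drop=True)
    off_mm = off_mm.where(suit_irr, 0.0).transpose("cell", "crop")
    wd_f, cons_f = withdrawal_factors(shares, eff)
    return IrrigationDemand(
        main_mm=main_mm.transpose("cell", "crop"),
        off_mm=off_mm,
        wd_factor=wd_f,
        cons_factor=cons_f,
    )


def annual_irrigation_demand(
    world: World,
    suitable: xr.DataArray,
    regressions: pd.DataFrame,
    eff: EfficiencyTable,
    dampening: float = 0.25,
) -> xr.Dataset:
    """Annual irrigation demand volumes for the world's irrigated crop areas.

    Returns per (cell, crop), in km^3/yr: consumption and withdrawal for a
    single-cropping variant (main season only, full irrigated physical
    area) and a multiple-cropping variant (main + off-season on the same
    area).  Consumption includes the consumptive share of conveyance
    losses.
    """
    d = irrigation_demand_per_ha(world, suitable, regressions, eff, dampening)
    area = world.crops["physical_area"].sel(regime="irrigated", drop=True)
    single_field = d.main_mm * area * MM_HA_TO_KM3
    mc_field = (d.main_mm + d.off_mm) * area * MM_HA_TO_KM3
    wd = xr.DataArray(d.wd_factor, coords={"cell": area.coords["cell"]}, dims=("cell",))
    cf = xr.DataArray(d.cons_factor, coords={"cell": area.coords["cell"]}, dims=("cell",))
    return xr.Dataset(
        {
            "single_consumption_km3": single_field * cf,
            "single_withdrawal_km3": single_field * wd,
            "mc_consumption_km3": mc_field * cf,
            "mc_withdrawal_km3": mc_field * wd,
        }
    )
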