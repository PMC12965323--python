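"""Off-season and annual multiple-cropping yields, and country calibration.

The crop model simulates each crop only in its prescribed main growing
season, while grass grows year-round.  The off-season yield of a crop is
approximated by scaling its main-season yield with the off-season-to-
main-season ratio of grass GPP (GPP summed over months outside vs inside
the season) and dampening the result by a fixed fraction (default 25%)
to absorb turnaround time between harvests and related losses.  The
off-season is a single aggregate: no distinction is made between one or
two extra cycles.

Annual yields follow: single cropping = main-season yield; multiple
cropping = main + off-season yield.  Off-season yield is forced to zero
wherever the cell is not suitable for multiple cropping under that water
regime.

Country calibration rescales modeled yields by one multiplicative factor
per country and crop so the area-weighted mean main-season yield matches
a reported yield, preserving within-country spatial patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import CalibrationError, MulticropError
from .world import World

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class YieldParams:
    offseason_dampening: float = 0.25
    calibration_cap: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.offseason_dampening <= 1.0:
            raise MulticropError("offseason_dampening must be in [0, 1]")


def offseason_ratio(gpp_12, season_months) -> float:
    """Off-season-to-main-season ratio of grass GPP (sums over months).

    Returns 0 when the off-season sum is 0.  A zero main-season sum with
    nonzero off-season GPP is degenerate (no meaningful main crop); it is
    logged and the ratio is 0.
    """
    arr = np.asarray(gpp_12, dtype=float)
    if arr.shape != (12,):
        raise MulticropError(f"expected 12 monthly values, got shape {arr.shape}")
    months = sorted(set(int(m) for m in season_months))
    if not months or not all(1 <= m <= 12 for m in months):
        raise MulticropError("season_months must be a nonempty subset of 1..12")
    mask = np.zeros(12, dtype=bool)
    mask[np.array(months) - 1] = True
    main = arr[mask].sum()
    off = arr[~mask].sum()
    if off == 0.0:
        return 0.0
    if main == 0.0:
        log.warning("degenerate season: main-season GPP sum is 0 with off-season GPP > 0")
        return 0.0
    return float(off / main)


def offseason_yield(y_main: float, ratio: float, params: YieldParams | None = None):
    """Off-season yield: main yield x GPP ratio x (1 - dampening)."""
    params = params or YieldParams()
    return y_main * ratio * (1.0 - params.offseason_dampening)


def ci_to_mc_share(physical_area, harvested_area):
    """Fraction of physical area under multiple cropping: min(CI - 1, 1).

    Cropping intensity CI = harvested / physical.  CI = 2 (or more; the
    off-season is one aggregate, so the share is capped at 1) means the
    whole physical area is harvested at least twice.
    """
    phys = np.asarray(physical_area, dtype=float)
    harv = np.asarray(harvested_area, dtype=float)
    if (phys < 0).any():
        raise MulticropError("physical_area must be >= 0")
    if (harv < np.where(phys > 0, phys, 0) - 1e-9).any():
        raise MulticropError("harvested_area must be >= physical_area (CI >= 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(phys > 0, harv / np.where(phys > 0, phys, 1.0), 1.0)
    share = np.clip(ci - 1.0, 0.0, 1.0)
    if np.isscalar(physical_area):
        return float(share)
    return share


def build_yield_table(
    world: World, suitable: xr.DataArray, params: YieldParams | None = None
) -> xr.Dataset:
    """Annual yield table, dims (cell, crop, regime).

    Variables: y_main, y_off, y_annual_single (= y_main) and y_annual_mc
    (= y_main + y_off), t DM/ha.  y_off is zero wherever *suitable* is
    False for the cell-regime.
    """
    params = params or YieldParams()
    gpp = world.gpp  # (cell, regime, month)
    season = world.crops["season"]  # (cell, crop, regime, month)
    main = gpp.where(season, 0.0).sum(dim="month")
    off = gpp.where(~season, 0.0).sum(dim="month")
    degenerate = (main == 0) & (off > 0)
    if bool(degenerate.any()):
        log.warning(
            "%d cell-crop-regime entries have zero main-season grass GPP; "
            "their off-season yield is set to 0",
            int(degenerate.sum()),
        )
    ratio = xr.where(main > 0, off / main.where(main > 0, 1.0), 0.0)
    y_main = world.crops["main_yield"]
    y_off = y_main * ratio * (1.0 - params.offseason_dampening)
    y_off = y_off.where(suitable, 0.0).transpose("cell", "crop", "regime")
    table = xr.Dataset(
        {
            "y_main": y_main,
            "y_off": y_off,
            "y_annual_single": y_main,
            "y_annual_mc": y_main + y_off,
        }
    )
    return table


def calibrate_yields(
    table: xr.Dataset,
    world: World,
    reported: pd.DataFrame,
    params: YieldParams | None = None,
) -> tuple[xr.Dataset, pd.DataFrame]:
    """Calibrate modeled yields to reported country-level yields.

    One multiplicative factor per country x crop, chosen so that the
    physical-area-weighted mean of the calibrated main-season yield
    (across regimes) equals the reported yield.  The factor is applied to
    y_main and y_off alike, so within-country cell-to-cell yield ratios
    are unchanged.  Country-crops with no area (reported NaN) get factor 1.
    Returns the calibrated table and the country x crop factor frame.
    """
    params = params or YieldParams()
    countries = sorted(world.grid["country"].unique())
    crop_names = world.crop_names
    area = world.crops["physical_area"].values  # (cell, crop, regime)
    y_main = table["y_main"].values
    country_per_cell = world.grid["country"].to_numpy()

    factors = pd.DataFrame(1.0, index=pd.Index(countries, name="country"), columns=crop_names)
    factor_per_cell = np.ones_like(y_main)
    for country in countries:
        in_c = country_per_cell == country
        for j, crop in enumerate(crop_names):
            a = area[in_c, j, :]
            tot = a.sum()
            if tot <= 0:
                continue
            rep = reported.loc[country, crop]
            if not np.isfinite(rep) or rep <= 0:
                raise CalibrationError(
                    f"reported yield missing or nonpositive for {country}/{crop} "
                    "with nonzero crop area"
                )
            modeled = (a * y_main[in_c, j, :]).sum() / tot
            if modeled <= 0:
                raise CalibrationError(
                    f"modeled area-weighted yield is 0 for {country}/{crop} "
                    f"but reported yield is {rep}"
                )
            f = rep / modeled
            if params.calibration_cap is not None:
                f = min(f, params.calibration_cap)
            factors.loc[country, crop] = f
            factor_per_cell[in_c, j, :] = f

    out = table.copy()
    for var in ("y_main", "y_off", "y_annual_single", "y_annual_mc"):
        out[var] = table[var] * xr.DataArray(
            factor_per_cell, coords=table["y_main"].coords, dims=table["y_main"].dims
        )
    return out, factors
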