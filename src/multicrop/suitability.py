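"""Multiple-cropping suitability from monthly grass GPP.

A month is a growing-period month when monthly grass GPP strictly exceeds
a threshold (default 100 g C m^-2, roughly 2.2 t DM/ha at a carbon
fraction of 0.45); a cell is suitable for multiple cropping under a water
regime when at least ``min_growing_months`` months (default 9) qualify
under that regime.  Suitability is assessed with unlimited irrigation
water supply; water constraints enter only later through allocation.

The threshold is strict ("exceeds"): a month at exactly the threshold
does not count.  Growing months need not be consecutive by default; a
cyclic consecutive-run variant is available via ``consecutive=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .errors import MulticropError


@dataclass(frozen=True)
class SuitabilityParams:
    gpp_threshold: float = 100.0  # g C m^-2 month^-1
    min_growing_months: int = 9
    consecutive: bool = False

    def __post_init__(self):
        if self.gpp_threshold < 0:
            raise MulticropError("gpp_threshold must be >= 0")
        if not 1 <= self.min_growing_months <= 13:
            # 13 is allowed as an explicit "never suitable" setting
            raise MulticropError("min_growing_months must be in 1..13")


def growing_period_months(gpp_12, params: SuitabilityParams | None = None) -> int:
    """Count months whose GPP strictly exceeds the threshold."""
    params = params or SuitabilityParams()
    arr = np.asarray(gpp_12, dtype=float)
    if arr.shape != (12,):
        raise MulticropError(f"expected 12 monthly values, got shape {arr.shape}")
    if (arr < 0).any():
        raise MulticropError("GPP values must be >= 0")
    return int((arr > params.gpp_threshold).sum())


def _longest_cyclic_run(mask: np.ndarray) -> np.ndarray:
    """Longest run of True along the last (month) axis, wrapping December->January."""
    doubled = np.concatenate([mask, mask], axis=-1).astype(int)
    best = np.zeros(mask.shape[:-1], dtype=int)
    run = np.zeros(mask.shape[:-1], dtype=int)
    for m in range(doubled.shape[-1]):
        run = (run + 1) * doubled[..., m]
        best = np.maximum(best, run)
    return np.minimum(best, mask.shape[-1])


def classify_suitability(
    gpp: xr.DataArray, params: SuitabilityParams | None = None
) -> xr.DataArray:
    """Boolean suitability per (cell, regime) from gpp dims (cell, regime, month)."""
    params = params or SuitabilityParams()
    if "month" not in gpp.dims or gpp.sizes["month"] != 12:
        raise MulticropError("gpp must carry a 12-entry 'month' dimension")
    above = gpp > params.gpp_threshold
    if params.consecutive:
        ordered = above.transpose(..., "month").values
        counts_np = _longest_cyclic_run(ordered)
        counts = xr.DataArray(
            counts_np,
            coords={d: gpp.coords[d] for d in gpp.dims if d != "month"},
            dims=[d for d in gpp.dims if d != "month"],
        )
    else:
        counts = above.sum(dim="month")
    return (counts >= params.min_growing_months).rename("suitable")


def gpp_threshold_in_dm(
    threshold_gC_m2: float, carbon_fraction: float = 0.45
) -> float:
    """Convert a GPP threshold (g C m^-2) to dry-matter terms (t DM/ha).

    1 g m^-2 = 0.01 t/ha; dividing by the carbon fraction converts carbon
    mass to dry matter.  The default 100 g C m^-2 corresponds to about
    2.2 t DM/ha.
    """
    if not 0.0 < carbon_fraction <= 1.0:
        raise MulticropError("carbon_fraction must be in (0, 1]")
    if threshold_gC_m2 < 0:
        raise MulticropError("threshold must be >= 0")
    return threshold_gC_m2 / carbon_fraction * 0.01
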