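"""Seed-reproducible synthetic worlds for exercising the full pipeline.

The generator emulates the statistical structure of the gridded inputs the
analysis assumes, without any pretence of climatological realism:

* **Grass GPP seasonality.** Each cell gets a number of "warm" months
  (months whose potential GPP exceeds the 100 g C m^-2 suitability
  threshold with margin) and a number of "wet" months.  Irrigated GPP is
  the thermal potential (unlimited water supply); rainfed GPP is the same
  curve with a dry-season suppression factor outside the wet months.  This
  reproduces the mechanism the suitability rule keys on: irrigation
  removes the dry-season limitation, never the thermal one.
* **Strata.** Cells are planted in three climatic strata — rainfed-suitable
  (>= 9 warm months, all wet), irrigated-only-suitable (>= 9 warm months
  but < 9 wet) and unsuitable (< 9 warm months) — with configurable
  fractions, plus a water-scarce stratum realized by scaling runoff down
  in a random subset of basins.  Stratum labels are kept on the grid
  frame as generator bookkeeping for tests.
* **River basins.** Basins are compact random-walk blobs on a 0.5-degree
  lattice; the walk's attachment edges form a random spanning tree whose
  root is the basin outlet, so the downstream pointers are a forest by
  construction and neighboring river cells are spatially adjacent.
* **Yields and water.** Main-season crop yields are proportional to
  mean main-season grass GPP (plus lognormal noise, shared between
  regimes so irrigated >= rainfed); grass ET is proportional to GPP; crop
  consumptive irrigation water requirements are a noisy linear function
  of grass consumptive IWR, which is exactly the relationship the
  off-season regression is meant to recover.
* **Crop areas.** Cropland fraction is clustered by basin (a deliberately
  arbitrary choice of spatial covariance), split into fallow, rainfed and
  irrigated parts; cropping intensity above 1 (i.e. existing multiple
  cropping) is planted only in cell-regimes that are climatically
  suitable under the default threshold parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .config import REGIMES, SYSTEMS
from .errors import ConfigError
from .world import World

KM_PER_DEG = 111.194  # mean great-circle km per degree of latitude


@dataclass(frozen=True)
class GenConfig:
    """Generation parameters. Fractions are of cells/basins; units in names."""

    n_crops: int = 4
    n_countries: int = 3
    resolution_deg: float = 0.5
    # climatic strata (remainder of cells is unsuitable)
    frac_rainfed_suitable: float = 0.25
    frac_irrigated_only: float = 0.35
    frac_scarce_basins: float = 0.2
    scarce_runoff_factor: float = 0.01
    # GPP curve
    gpp_peak_range: tuple[float, float] = (180.0, 260.0)
    gpp_warm_floor: float = 120.0  # warm months land in [floor, peak]
    gpp_cold_ceiling: float = 80.0  # cold months land in (0, ceiling]
    dry_season_factor: float = 0.2  # rainfed GPP multiplier outside wet months
    gpp_noise_sd: float = 0.03  # multiplicative, clipped to +-10%
    # water
    et_per_gpp_mm: float = 0.35  # mm grass ET per g C m^-2 GPP
    crop_iwc_slope: float = 1.2
    crop_iwc_intercept_mm: float = 5.0
    crop_iwc_noise_mm: float = 5.0
    runoff_mm_wet: float = 300.0  # annual runoff depth for a fully wet cell
    nonag_withdrawal_frac: float = 0.05  # cap on non-ag withdrawal vs local runoff
    # crops and areas
    season_length_range: tuple[int, int] = (5, 7)
    yield_scale_range: tuple[float, float] = (2.0, 6.0)
    yield_noise_sd: float = 0.15
    cropland_frac_range: tuple[float, float] = (0.1, 0.6)
    fallow_share_range: tuple[float, float] = (0.1, 0.3)
    irr_frac_beta: tuple[float, float] = (2.0, 5.0)
    irrigated_only_irr_boost: float = 0.35
    ci_excess_max: float = 0.8  # CI drawn in [1, 1 + ci_excess_max]
    mc_participation: float = 0.6  # prob. a suitable cell-crop-regime has CI > 1
    reported_factor_range: tuple[float, float] = (0.6, 1.1)

    def validate(self) -> None:
        if self.n_crops < 1:
            raise ConfigError("n_crops: must be >= 1")
        if self.n_countries < 1:
            raise ConfigError("n_countries: must be >= 1")
        for name in ("frac_rainfed_suitable", "frac_irrigated_only",
                     "frac_scarce_basins", "dry_season_factor",
                     "mc_participation", "nonag_withdrawal_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v}: must be in [0, 1]")
        if self.frac_rainfed_suitable + self.frac_irrigated_only > 1.0 + 1e-12:
            raise ConfigError("stratum fractions: must sum to <= 1")
        if self.dry_season_factor > 0.3:
            raise ConfigError(
                "dry_season_factor: must be <= 0.3 so dry months stay below the "
                "default 100 g C m^-2 threshold"
            )
        if not 0 < self.gpp_cold_ceiling < 100.0 < self.gpp_warm_floor:
            raise ConfigError(
                "gpp_warm_floor/gpp_cold_ceiling must bracket 100 g C m^-2"
            )
        lo, hi = self.gpp_peak_range
        if not self.gpp_warm_floor <= lo <= hi <= 300.0:
            raise ConfigError("gpp_peak_range: need warm_floor <= lo <= hi <= 300")
        if not 0 < self.ci_excess_max <= 1.0:
            raise ConfigError("ci_excess_max: must be in (0, 1]")
        lo, hi = self.season_length_range
        if not 1 <= lo <= hi <= 12:
            raise ConfigError("season_length_range: must lie within 1..12")
        lo, hi = self.cropland_frac_range
        if not 0 < lo <= hi <= 0.9:
            raise ConfigError("cropland_frac_range: must lie within (0, 0.9]")
        lo, hi = self.fallow_share_range
        if not 0 <= lo <= hi < 1:
            raise ConfigError("fallow_share_range: must lie within [0, 1)")
        for name in ("et_per_gpp_mm", "crop_iwc_slope", "runoff_mm_wet"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")


STRATA = ("rainfed_suitable", "irrigated_only", "unsuitable")


def generate_world(
    seed: int, n_cells: int, n_basins: int, config: GenConfig | None = None
) -> World:
    """Generate a synthetic :class:`World`; a pure function of its arguments."""
    cfg = config or GenConfig()
    cfg.validate()
    if not n_cells >= n_basins >= 1:
        raise ConfigError(f"need n_cells >= n_basins >= 1, got {n_cells}, {n_basins}")
    rng = np.random.default_rng(seed)

    lat, lon, downstream, basin_id = _build_basins(rng, n_cells, n_basins, cfg)
    cell_ids = np.arange(n_cells)
    area_km2 = (KM_PER_DEG * cfg.resolution_deg) ** 2 * np.cos(np.radians(lat))
    cell_area = area_km2 * 100.0  # ha

    country = np.array(
        [f"C{cell * cfg.n_countries // n_cells:02d}" for cell in cell_ids]
    )
    stratum = rng.choice(
        STRATA,
        size=n_cells,
        p=[
            cfg.frac_rainfed_suitable,
            cfg.frac_irrigated_only,
            1.0 - cfg.frac_rainfed_suitable - cfg.frac_irrigated_only,
        ],
    )

    gpp_irr, gpp_rf, month_order, n_wet = _build_gpp(rng, stratum, cfg)
    months = np.arange(1, 13)
    gpp = xr.DataArray(
        np.stack([gpp_rf, gpp_irr], axis=1),
        coords={"cell": cell_ids, "regime": list(REGIMES), "month": months},
        dims=("cell", "regime", "month"),
        name="gpp",
    )
    grass_et = (gpp * cfg.et_per_gpp_mm).rename("grass_et")

    crops = _build_crops(rng, cfg, cell_ids, stratum, gpp_irr, gpp_rf, month_order)

    # areas: cropland fraction clustered by basin
    basin_base = rng.uniform(*cfg.cropland_frac_range, size=n_basins)
    frac = np.clip(basin_base[basin_id] + rng.normal(0, 0.05, n_cells), 0.02, 0.9)
    physical_total = frac * cell_area
    fallow = rng.uniform(*cfg.fallow_share_range, size=n_cells) * physical_total
    active = physical_total - fallow
    a, b = cfg.irr_frac_beta
    irr_frac = np.clip(
        rng.beta(a, b, n_cells)
        + cfg.irrigated_only_irr_boost * (stratum == "irrigated_only"),
        0.0,
        0.95,
    )
    crop_share = rng.dirichlet(np.full(cfg.n_crops, 2.0), size=n_cells)
    phys = np.empty((n_cells, cfg.n_crops, 2))
    phys[:, :, 0] = active[:, None] * (1 - irr_frac)[:, None] * crop_share
    phys[:, :, 1] = active[:, None] * irr_frac[:, None] * crop_share
    # cropping intensity: existing multiple cropping only where suitable
    suitable = np.stack(
        [stratum == "rainfed_suitable",
         np.isin(stratum, ("rainfed_suitable", "irrigated_only"))],
        axis=1,
    )  # (cell, regime)
    participates = rng.random((n_cells, cfg.n_crops, 2)) < cfg.mc_participation
    ci_excess = rng.uniform(0, cfg.ci_excess_max, size=(n_cells, cfg.n_crops, 2))
    ci = 1.0 + ci_excess * participates * suitable[:, None, :]
    harv = phys * ci
    crops["physical_area"] = (("cell", "crop", "regime"), phys)
    crops["harvested_area"] = (("cell", "crop", "regime"), harv)

    shares = rng.dirichlet((4.0, 2.0, 1.0), size=n_cells)
    system_shares = pd.DataFrame(shares, columns=list(SYSTEMS), index=cell_ids)
    system_shares.index.name = None

    # runoff: wetter cells shed more water; some basins are water-scarce
    wet_frac = n_wet / 12.0
    runoff_mm = cfg.runoff_mm_wet * wet_frac * rng.lognormal(0.0, 0.3, n_cells)
    runoff = runoff_mm * cell_area * 1e-8  # km^3/yr
    n_scarce = int(np.floor(cfg.frac_scarce_basins * n_basins))
    scarce_basins = sorted(
        int(x) for x in rng.choice(n_basins, size=n_scarce, replace=False)
    )
    runoff[np.isin(basin_id, scarce_basins)] *= cfg.scarce_runoff_factor

    nonag_wd = rng.uniform(0, cfg.nonag_withdrawal_frac, n_cells) * runoff
    nonag = pd.DataFrame(
        {
            "withdrawal_km3": nonag_wd,
            "consumption_km3": rng.uniform(0.3, 0.7, n_cells) * nonag_wd,
        },
        index=cell_ids,
    )
    nonag.index.name = None

    grid = pd.DataFrame(
        {
            "lat": lat,
            "lon": lon,
            "cell_area_ha": cell_area,
            "country": country,
            "stratum": stratum,
        },
        index=cell_ids,
    )
    grid.index.name = None

    reported = _build_reported_yields(rng, cfg, grid, crops)

    world = World(
        grid=grid,
        downstream=downstream,
        basin_id=basin_id,
        runoff=runoff,
        gpp=gpp,
        grass_et=grass_et,
        crops=crops,
        fallow_area=fallow,
        system_shares=system_shares,
        nonag=nonag,
        reported_yield=reported,
        meta={
            "seed": int(seed),
            "n_cells": int(n_cells),
            "n_basins": int(n_basins),
            "scarce_basins": scarce_basins,
            "config": _config_dict(cfg),
        },
    )
    world.validate()
    return world


def _config_dict(cfg: GenConfig) -> dict:
    out = {}
    for k, v in asdict(cfg).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def config_from_dict(raw: dict) -> GenConfig:
    """Rebuild a GenConfig from its serialized form (lists back to tuples)."""
    kwargs = {}
    for f in GenConfig.__dataclass_fields__.values():
        if f.name in raw:
            v = raw[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    unknown = set(raw) - set(GenConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown generation keys: {sorted(unknown)}")
    cfg = GenConfig(**kwargs)
    cfg.validate()
    return cfg


def _build_basins(rng, n_cells, n_basins, cfg):
    """Compact random-walk basins on disjoint longitude windows; spanning trees."""
    sizes = np.ones(n_basins, dtype=int)
    extra = rng.multinomial(n_cells - n_basins, np.full(n_basins, 1.0 / n_basins))
    sizes += extra
    res = cfg.resolution_deg
    window = 360.0 / n_basins
    lat_list, lon_list, down_list, basin_list = [], [], [], []
    offset = 0
    for b in range(n_basins):
        size = sizes[b]
        c_lat = rng.uniform(-50, 50)
        c_lon = -180.0 + (b + 0.5) * window
        # grid-walk: cells at integer offsets from the basin center
        occupied = {(0, 0)}
        coords = [(0, 0)]
        parents = [-1]
        while len(coords) < size:
            i = int(rng.integers(len(coords)))
            ci, cj = coords[i]
            di, dj = ((1, 0), (-1, 0), (0, 1), (0, -1))[int(rng.integers(4))]
            cand = (ci + di, cj + dj)
            if cand in occupied:
                continue
            if abs(cand[0]) * res > 9.5 or abs(cand[1]) * res > window / 2 - res:
                continue
            occupied.add(cand)
            coords.append(cand)
            parents.append(i)
        for i, (ci, cj) in enumerate(coords):
            lat_list.append(np.clip(c_lat + ci * res, -60.0, 60.0))
            lon_list.append(c_lon + cj * res)
            down_list.append(-1 if parents[i] == -1 else offset + parents[i])
            basin_list.append(b)
        offset += size
    return (
        np.array(lat_list),
        np.array(lon_list),
        np.array(down_list, dtype=int),
        np.array(basin_list, dtype=int),
    )


def _build_gpp(rng, stratum, cfg):
    """Monthly GPP per cell and regime, with stratum-controlled month counts."""
    n = len(stratum)
    n_warm = np.where(
        stratum == "unsuitable", rng.integers(4, 8, n), rng.integers(9, 13, n)
    )
    n_wet = np.where(
        stratum == "rainfed_suitable",
        n_warm,
        np.minimum(rng.integers(2, 8, n), n_warm),
    )
    peak_month = rng.integers(1, 13, n)
    peak = rng.uniform(*cfg.gpp_peak_range, size=n)

    months = np.arange(1, 13)
    # cyclic distance to the peak month, ties broken toward earlier months
    dist = np.abs(((months[None, :] - peak_month[:, None]) + 6) % 12 - 6)
    order = np.argsort(dist + months[None, :] * 1e-3, axis=1)  # warmth ranking

    gpp_pot = np.empty((n, 12))
    rank_vals = np.empty(12)
    for i in range(n):
        w = n_warm[i]
        rank_vals[:w] = np.linspace(peak[i], cfg.gpp_warm_floor, w)
        rank_vals[w:] = np.linspace(cfg.gpp_cold_ceiling, 10.0, 12 - w)
        gpp_pot[i, order[i]] = rank_vals[:12]

    noise = np.clip(1.0 + rng.normal(0, cfg.gpp_noise_sd, (n, 12)), 0.9, 1.1)
    gpp_irr = gpp_pot * noise

    wet_mask = np.zeros((n, 12), dtype=bool)
    for i in range(n):
        wet_mask[i, order[i, : n_wet[i]]] = True
    gpp_rf = gpp_irr * np.where(wet_mask, 1.0, cfg.dry_season_factor)
    return gpp_irr, gpp_rf, order, n_wet


def _build_crops(rng, cfg, cell_ids, stratum, gpp_irr, gpp_rf, month_order):
    """Per-crop seasons, main yields and ET components as an xarray Dataset."""
    n = len(cell_ids)
    k = cfg.n_crops
    crop_names = [f"crop{j}" for j in range(k)]
    lo, hi = cfg.season_length_range
    season_len = rng.integers(lo, hi + 1, size=k)
    yscale = rng.uniform(*cfg.yield_scale_range, size=k)

    season = np.zeros((n, k, 2, 12), dtype=bool)
    for j in range(k):
        # crop j grows in its season-length warmest months (same both regimes)
        for i in range(n):
            season[i, j, :, month_order[i, : season_len[j]]] = True

    ynoise = rng.lognormal(0.0, cfg.yield_noise_sd, size=(n, k))
    y = np.empty((n, k, 2))
    giwc_main = np.empty((n, k))
    grass_rf_season = np.empty((n, k))
    for j in range(k):
        m = season[:, j, 1, :]
        mean_irr = (gpp_irr * m).sum(axis=1) / m.sum(axis=1)
        mean_rf = (gpp_rf * m).sum(axis=1) / m.sum(axis=1)
        y[:, j, 1] = yscale[j] * mean_irr / 200.0 * ynoise[:, j]
        y[:, j, 0] = yscale[j] * mean_rf / 200.0 * ynoise[:, j]
        giwc_main[:, j] = cfg.et_per_gpp_mm * ((gpp_irr - gpp_rf) * m).sum(axis=1)
        grass_rf_season[:, j] = cfg.et_per_gpp_mm * (gpp_rf * m).sum(axis=1)

    crop_iwc = np.clip(
        cfg.crop_iwc_slope * giwc_main
        + cfg.crop_iwc_intercept_mm
        + rng.normal(0, cfg.crop_iwc_noise_mm, size=(n, k)),
        0.0,
        None,
    )
    base = grass_rf_season * rng.uniform(0.9, 1.1, size=(n, k))
    frac = np.array([0.6, 0.3, 0.1])  # T/E/I split of total ET
    comp = {}
    for idx, name in enumerate(("transpiration", "evaporation", "interception")):
        arr = np.empty((n, k, 2))
        arr[:, :, 0] = base * frac[idx]
        arr[:, :, 1] = base * frac[idx] + crop_iwc * frac[idx]
        comp[name] = arr

    months = np.arange(1, 13)
    ds = xr.Dataset(
        {
            "main_yield": (("cell", "crop", "regime"), y),
            "transpiration": (("cell", "crop", "regime"), comp["transpiration"]),
            "evaporation": (("cell", "crop", "regime"), comp["evaporation"]),
            "interception": (("cell", "crop", "regime"), comp["interception"]),
            "season": (("cell", "crop", "regime", "month"), season),
        },
        coords={
            "cell": cell_ids,
            "crop": crop_names,
            "regime": list(REGIMES),
            "month": months,
        },
    )
    return ds


def _build_reported_yields(rng, cfg, grid, crops) -> pd.DataFrame:
    """Country x crop reported yields: modeled area-weighted mean x hidden factor."""
    countries = sorted(grid["country"].unique())
    crop_names = [str(c) for c in crops.coords["crop"].values]
    y = crops["main_yield"].values
    a = crops["physical_area"].values
    rows = {}
    for country in countries:
        in_c = (grid["country"] == country).to_numpy()
        vals = []
        for j in range(len(crop_names)):
            area = a[in_c, j, :]
            tot = area.sum()
            if tot <= 0:
                vals.append(np.nan)
                continue
            mean = (area * y[in_c, j, :]).sum() / tot
            factor = rng.uniform(*cfg.reported_factor_range)
            vals.append(mean * factor)
        rows[country] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=crop_names)
    df.index.name = "country"
    return df
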