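"""The ``World`` container: every gridded input layer the pipeline consumes.

A world bundles, on a common set of grid cells:

* the grid itself (cell centers, cell areas, synthetic countries),
* a river network (downstream pointers forming a forest, basin labels,
  annual runoff),
* monthly grass GPP and grass evapotranspiration under rainfed and
  irrigated (unlimited water supply) conditions,
* per-crop main-season yields, ET components, growing seasons, and
  physical/harvested areas split by water regime, plus fallow land,
* irrigation-system shares, non-agricultural water demand, and
  country-level reported yields for calibration.

Worlds are either generated synthetically (:mod:`multicrop.synth`) or
loaded from a run directory of tidy text files.  Serialization uses
17-significant-digit decimal text so that float64 layers round-trip
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import REGIMES, SYSTEMS
from .errors import WorldFormatError

_FLOAT_FMT = "%.17g"


@dataclass
class World:
    """Complete input bundle for one model run. See module docstring."""

    #: per-cell frame indexed by cell_id: lat, lon, cell_area_ha, country, stratum
    grid: pd.DataFrame
    #: downstream cell_id per cell, -1 at basin outlets
    downstream: np.ndarray
    #: basin label per cell
    basin_id: np.ndarray
    #: annual runoff per cell, km^3/yr
    runoff: np.ndarray
    #: grass GPP, dims (cell, regime, month), g C m^-2 month^-1
    gpp: xr.DataArray
    #: grass evapotranspiration, dims (cell, regime, month), mm month^-1
    grass_et: xr.DataArray
    #: per-crop layers, dims (cell, crop, regime); plus season(cell,crop,regime,month)
    crops: xr.Dataset
    #: fallow land per cell, ha
    fallow_area: np.ndarray
    #: irrigation-system shares, cell x (surface, sprinkler, drip), rows sum to 1
    system_shares: pd.DataFrame
    #: non-agricultural demand per cell: withdrawal_km3, consumption_km3
    nonag: pd.DataFrame
    #: reported country-level yields, country x crop, t DM/ha (NaN = no area)
    reported_yield: pd.DataFrame
    #: provenance: generation config and seed
    meta: dict = field(default_factory=dict)

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.grid)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.grid.index.to_numpy()

    @property
    def crop_names(self) -> list[str]:
        return [str(c) for c in self.crops.coords["crop"].values]

    @property
    def lat(self) -> np.ndarray:
        return self.grid["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.grid["lon"].to_numpy()

    @property
    def cell_area(self) -> np.ndarray:
        return self.grid["cell_area_ha"].to_numpy()

    def validate(self) -> None:
        """Check every structural invariant; raise WorldFormatError on violation."""
        if self.grid.index.duplicated().any():
            raise WorldFormatError("grid: duplicate cell_ids")
        if (self.grid["cell_area_ha"] <= 0).any():
            raise WorldFormatError("grid: cell_area must be > 0")
        n = self.n_cells
        for name, arr in (
            ("downstream", self.downstream),
            ("basin_id", self.basin_id),
            ("runoff", self.runoff),
            ("fallow_area", self.fallow_area),
        ):
            if len(arr) != n:
                raise WorldFormatError(f"{name}: length {len(arr)} != n_cells {n}")
        if (self.runoff < 0).any():
            raise WorldFormatError("runoff: negative values")
        if (self.fallow_area < 0).any():
            raise WorldFormatError("fallow_area: negative values")
        _check_forest(self.downstream, self.basin_id)
        if (self.gpp.values < 0).any():
            raise WorldFormatError("gpp: negative values")
        gpp_irr = self.gpp.sel(regime="irrigated").values
        gpp_rf = self.gpp.sel(regime="rainfed").values
        if (gpp_irr < gpp_rf - 1e-9).any():
            raise WorldFormatError("gpp: irrigated must be >= rainfed per cell-month")
        phys = self.crops["physical_area"].values
        harv = self.crops["harvested_area"].values
        if (phys < 0).any():
            raise WorldFormatError("physical_area: negative values")
        active = phys > 0
        if (harv[active] < phys[active] - 1e-9).any():
            raise WorldFormatError("harvested_area: must be >= physical_area (CI >= 1)")
        total = phys.sum(axis=(1, 2)) + self.fallow_area
        if (total > self.cell_area * (1 + 1e-9)).any():
            raise WorldFormatError("areas: physical + fallow exceeds cell_area")
        if (self.crops["main_yield"].values < 0).any():
            raise WorldFormatError("main_yield: negative values")
        if not self.crops["season"].any(dim="month").all():
            raise WorldFormatError("season: every cell-crop-regime needs >= 1 month")
        shares = self.system_shares[list(SYSTEMS)].to_numpy()
        if (shares < -1e-12).any() or (shares > 1 + 1e-12).any():
            raise WorldFormatError("system_shares: values outside [0, 1]")
        if np.abs(shares.sum(axis=1) - 1.0).max() > 1e-9:
            raise WorldFormatError("system_shares: rows must sum to 1")
        wd = self.nonag["withdrawal_km3"].to_numpy()
        cons = self.nonag["consumption_km3"].to_numpy()
        if (cons < -1e-12).any() or (cons > wd + 1e-12).any():
            raise WorldFormatError("nonag: need 0 <= consumption <= withdrawal")

    def equals(self, other: "World", tol: float = 1e-12) -> bool:
        """Layer-wise equality within an absolute float tolerance."""
        try:
            pd.testing.assert_frame_equal(self.grid, other.grid, atol=tol, rtol=0)
            pd.testing.assert_frame_equal(
                self.system_shares, other.system_shares, atol=tol, rtol=0
            )
            pd.testing.assert_frame_equal(self.nonag, other.nonag, atol=tol, rtol=0)
            pd.testing.assert_frame_equal(
                self.reported_yield, other.reported_yield, atol=tol, rtol=0
            )
        except AssertionError:
            return False
        return (
            np.array_equal(self.downstream, other.downstream)
            and np.array_equal(self.basin_id, other.basin_id)
            and np.allclose(self.runoff, other.runoff, atol=tol, rtol=0)
            and np.allclose(self.fallow_area, other.fallow_area, atol=tol, rtol=0)
            and np.allclose(self.gpp.values, other.gpp.values, atol=tol, rtol=0)
            and np.allclose(self.grass_et.values, other.grass_et.values, atol=tol, rtol=0)
            and self.crop_names == other.crop_names
            and all(
                np.allclose(
                    self.crops[v].values, other.crops[v].values, atol=tol, rtol=0
                )
                for v in _CROP_FLOAT_VARS
            )
            and np.array_equal(self.crops["season"].values, other.crops["season"].values)
        )


def _check_forest(downstream: np.ndarray, basin_id: np.ndarray) -> None:
    """Downstream pointers must form a forest; basins must match tree roots."""
    n = len(downstream)
    root = np.full(n, -1, dtype=int)
    for start in range(n):
        seen = set()
        c = start
        while downstream[c] != -1:
            if c in seen:
                raise WorldFormatError("downstream: cycle detected in river network")
            seen.add(c)
            c = int(downstream[c])
            if not 0 <= c < n:
                raise WorldFormatError("downstream: pointer outside the grid")
        root[start] = c
    for start in range(n):
        if basin_id[start] != basin_id[root[start]]:
            raise WorldFormatError("basin_id: cells must share their root's basin")


_CROP_FLOAT_VARS = (
    "main_yield",
    "transpiration",
    "evaporation",
    "interception",
    "physical_area",
    "harvested_area",
)

#: layer name -> filename; load errors name the layer.
LAYER_FILES = {
    "grid": "grid.csv",
    "network": "network.csv",
    "runoff": "runoff.csv",
    "gpp": "gpp.csv",
    "grass_et": "grass_et.csv",
    "crops": "crops.csv",
    "seasons": "seasons.csv",
    "cell_scalars": "cell_scalars.csv",
    "reported_yields": "reported_yields.csv",
    "meta": "meta.json",
}


def save_world(world: World, directory) -> None:
    """Write every layer of *world* as tidy text files under *directory*."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    grid = world.grid.reset_index().rename(columns={"index": "cell"})
    grid.columns = ["cell"] + list(world.grid.columns)
    grid.to_csv(d / LAYER_FILES["grid"], index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(
        {
            "cell": world.cell_ids,
            "downstream": world.downstream,
            "basin_id": world.basin_id,
        }
    ).to_csv(d / LAYER_FILES["network"], index=False)

    pd.DataFrame({"cell": world.cell_ids, "runoff_km3": world.runoff}).to_csv(
        d / LAYER_FILES["runoff"], index=False, float_format=_FLOAT_FMT
    )

    for key, da, col in (
        ("gpp", world.gpp, "gpp_gC_m2"),
        ("grass_et", world.grass_et, "et_mm"),
    ):
        df = da.to_dataframe(name=col).reset_index()
        df.to_csv(d / LAYER_FILES[key], index=False, float_format=_FLOAT_FMT)

    crops = (
        world.crops[list(_CROP_FLOAT_VARS)]
        .to_dataframe()
        .reset_index()
    )
    crops.to_csv(d / LAYER_FILES["crops"], index=False, float_format=_FLOAT_FMT)

    season = world.crops["season"]
    rows = []
    for cell in world.cell_ids:
        for crop in world.crop_names:
            for regime in REGIMES:
                months = season.sel(cell=cell, crop=crop, regime=regime).values
                idx = np.nonzero(months)[0] + 1
                rows.append(
                    {
                        "cell": cell,
                        "crop": crop,
                        "regime": regime,
                        "months": ";".join(str(m) for m in idx),
                    }
                )
    pd.DataFrame(rows).to_csv(d / LAYER_FILES["seasons"], index=False)

    scalars = pd.DataFrame({"cell": world.cell_ids, "fallow_area_ha": world.fallow_area})
    for s in SYSTEMS:
        scalars[f"share_{s}"] = world.system_shares[s].to_numpy()
    scalars["nonag_withdrawal_km3"] = world.nonag["withdrawal_km3"].to_numpy()
    scalars["nonag_consumption_km3"] = world.nonag["consumption_km3"].to_numpy()
    scalars.to_csv(d / LAYER_FILES["cell_scalars"], index=False, float_format=_FLOAT_FMT)

    ry = world.reported_yield.reset_index().melt(
        id_vars="country", var_name="crop", value_name="yield_t_dm_ha"
    )
    ry.to_csv(d / LAYER_FILES["reported_yields"], index=False, float_format=_FLOAT_FMT)

    with open(d / LAYER_FILES["meta"], "w", encoding="utf-8") as fh:
        json.dump(world.meta, fh, indent=1, sort_keys=True)


def load_world(directory) -> World:
    """Read a world written by :func:`save_world`; errors name the missing layer."""
    d = Path(directory)
    missing = [name for name, fn in LAYER_FILES.items() if not (d / fn).exists()]
    if missing:
        raise WorldFormatError(
            f"world directory {d} is missing layer(s): {', '.join(missing)}"
        )
    try:
        grid = pd.read_csv(d / LAYER_FILES["grid"], float_precision="round_trip").set_index("cell")
        grid.index.name = None
        network = pd.read_csv(d / LAYER_FILES["network"])
        runoff = pd.read_csv(d / LAYER_FILES["runoff"], float_precision="round_trip")
        gpp = _load_grid_layer(d / LAYER_FILES["gpp"], "gpp_gC_m2")
        grass_et = _load_grid_layer(d / LAYER_FILES["grass_et"], "et_mm")
        crops_df = pd.read_csv(d / LAYER_FILES["crops"], float_precision="round_trip")
        seasons = pd.read_csv(d / LAYER_FILES["seasons"])
        scalars = pd.read_csv(d / LAYER_FILES["cell_scalars"], float_precision="round_trip")
        ry = pd.read_csv(d / LAYER_FILES["reported_yields"], float_precision="round_trip")
        with open(d / LAYER_FILES["meta"], "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    except (ValueError, KeyError) as exc:
        raise WorldFormatError(f"failed parsing world layers: {exc}") from exc

    crops = crops_df.set_index(["cell", "crop", "regime"]).to_xarray()
    crops = crops.reindex(regime=list(REGIMES))
    months = np.arange(1, 13)
    season = xr.DataArray(
        np.zeros(
            (crops.sizes["cell"], crops.sizes["crop"], crops.sizes["regime"], 12),
            dtype=bool,
        ),
        coords={
            "cell": crops.coords["cell"],
            "crop": crops.coords["crop"],
            "regime": crops.coords["regime"],
            "month": months,
        },
        dims=("cell", "crop", "regime", "month"),
    )
    cell_pos = {c: i for i, c in enumerate(crops.coords["cell"].values)}
    crop_pos = {c: i for i, c in enumerate(crops.coords["crop"].values)}
    regime_pos = {r: i for i, r in enumerate(REGIMES)}
    sv = season.values
    for row in seasons.itertuples(index=False):
        ms = [int(m) for m in str(row.months).split(";") if m]
        if not ms:
            raise WorldFormatError("seasons: empty month set")
        sv[cell_pos[row.cell], crop_pos[row.crop], regime_pos[row.regime], :] = False
        for m in ms:
            sv[cell_pos[row.cell], crop_pos[row.crop], regime_pos[row.regime], m - 1] = True
    crops["season"] = season

    system_shares = pd.DataFrame(
        {s: scalars[f"share_{s}"].to_numpy() for s in SYSTEMS},
        index=scalars["cell"].to_numpy(),
    )
    system_shares.index.name = None
    nonag = pd.DataFrame(
        {
            "withdrawal_km3": scalars["nonag_withdrawal_km3"].to_numpy(),
            "consumption_km3": scalars["nonag_consumption_km3"].to_numpy(),
        },
        index=scalars["cell"].to_numpy(),
    )
    nonag.index.name = None
    reported = ry.pivot(index="country", columns="crop", values="yield_t_dm_ha")
    reported = reported[sorted(reported.columns)]
    reported.columns.name = None

    world = World(
        grid=grid,
        downstream=network["downstream"].to_numpy(),
        basin_id=network["basin_id"].to_numpy(),
        runoff=runoff["runoff_km3"].to_numpy(),
        gpp=gpp,
        grass_et=grass_et,
        crops=crops,
        fallow_area=scalars["fallow_area_ha"].to_numpy(),
        system_shares=system_shares,
        nonag=nonag,
        reported_yield=reported,
        meta=meta,
    )
    world.validate()
    return world


def _load_grid_layer(path: Path, col: str) -> xr.DataArray:
    df = pd.read_csv(path, float_precision="round_trip")
    da = df.set_index(["cell", "regime", "month"])[col].to_xarray()
    return da.reindex(regime=list(REGIMES))
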