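import numpy as np
import pandas as pd
import pytest
import xarray as xr

from multicrop import GenConfig, generate_world, run_pipeline
from multicrop.config import REGIMES, SYSTEMS
from multicrop.synth import KM_PER_DEG
from multicrop.world import World


@pytest.fixture(scope="session")
def world_small():
    return generate_world(1, 60, 5)


@pytest.fixture(scope="session")
def pipeline_small(world_small):
    return run_pipeline(world_small)


def make_world(
    lat,
    lon,
    downstream,
    basin_id,
    runoff,
    gpp_rf,
    gpp_irr,
    season,
    y_main,
    physical,
    harvested,
    et_rf=None,
    et_irr=None,
    fallow=None,
    shares=None,
    nonag_w=None,
    nonag_c=None,
    grass_et_factor=0.35,
    country=None,
    reported=None,
):
    """Hand-built World for worked examples.

    gpp_rf/gpp_irr: (n, 12); season: (n, k, 12) bool (same for both regimes);
    y_main, physical, harvested: (n, k, 2) with regime order (rainfed,
    irrigated); et_rf/et_irr: (n, k) total crop ET over the irrigated season,
    split 60/30/10 into T/E/I.
    """
    lat = np.asarray(lat, dtype=float)
    n = len(lat)
    gpp_rf = np.asarray(gpp_rf, dtype=float)
    gpp_irr = np.asarray(gpp_irr, dtype=float)
    season = np.asarray(season, dtype=bool)
    k = season.shape[1]
    y_main = np.asarray(y_main, dtype=float)
    physical = np.asarray(physical, dtype=float)
    harvested = np.asarray(harvested, dtype=float)
    et_rf = np.zeros((n, k)) if et_rf is None else np.asarray(et_rf, dtype=float)
    et_irr = et_rf if et_irr is None else np.asarray(et_irr, dtype=float)

    cells = np.arange(n)
    area = (KM_PER_DEG * 0.5) ** 2 * np.cos(np.radians(lat)) * 100.0
    grid = pd.DataFrame(
        {
            "lat": lat,
            "lon": np.asarray(lon, dtype=float),
            "cell_area_ha": area,
            "country": country if country is not None else ["C00"] * n,
            "stratum": ["manual"] * n,
        },
        index=cells,
    )
    grid.index.name = None
    months = np.arange(1, 13)
    gpp = xr.DataArray(
        np.stack([gpp_rf, gpp_irr], axis=1),
        coords={"cell": cells, "regime": list(REGIMES), "month": months},
        dims=("cell", "regime", "month"),
    )
    crop_names = [f"crop{j}" for j in range(k)]
    frac = np.array([0.6, 0.3, 0.1])
    comp = {}
    for i, name in enumerate(("transpiration", "evaporation", "interception")):
        arr = np.empty((n, k, 2))
        arr[:, :, 0] = et_rf * frac[i]
        arr[:, :, 1] = et_irr * frac[i]
        comp[name] = arr
    crops = xr.Dataset(
        {
            "main_yield": (("cell", "crop", "regime"), y_main),
            "transpiration": (("cell", "crop", "regime"), comp["transpiration"]),
            "evaporation": (("cell", "crop", "regime"), comp["evaporation"]),
            "interception": (("cell", "crop", "regime"), comp["interception"]),
            "season": (
                ("cell", "crop", "regime", "month"),
                np.repeat(season[:, :, None, :], 2, axis=2),
            ),
            "physical_area": (("cell", "crop", "regime"), physical),
            "harvested_area": (("cell", "crop", "regime"), harvested),
        },
        coords={
            "cell": cells,
            "crop": crop_names,
            "regime": list(REGIMES),
            "month": months,
        },
    )
    if shares is None:
        shares = np.tile([1.0, 0.0, 0.0], (n, 1))
    system_shares = pd.DataFrame(np.asarray(shares, dtype=float), columns=list(SYSTEMS), index=cells)
    system_shares.index.name = None
    nonag = pd.DataFrame(
        {
            "withdrawal_km3": np.zeros(n) if nonag_w is None else np.asarray(nonag_w, float),
            "consumption_km3": np.zeros(n) if nonag_c is None else np.asarray(nonag_c, float),
        },
        index=cells,
    )
    nonag.index.name = None
    if reported is None:
        # area-weighted modeled mean => calibration factors of exactly 1
        countries = sorted(set(grid["country"]))
        vals = {}
        for c in countries:
            in_c = (grid["country"] == c).to_numpy()
            row = []
            for j in range(k):
                a = physical[in_c, j, :]
                row.append(
                    (a * y_main[in_c, j, :]).sum() / a.sum() if a.sum() > 0 else np.nan
                )
            vals[c] = row
        reported = pd.DataFrame.from_dict(vals, orient="index", columns=crop_names)
        reported.index.name = "country"
    world = World(
        grid=grid,
        downstream=np.asarray(downstream, dtype=int),
        basin_id=np.asarray(basin_id, dtype=int),
        runoff=np.asarray(runoff, dtype=float),
        gpp=gpp,
        grass_et=gpp * grass_et_factor,
        crops=crops,
        fallow_area=np.zeros(n) if fallow is None else np.asarray(fallow, float),
        system_shares=system_shares,
        nonag=nonag,
        reported_yield=reported,
        meta={"origin": "test fixture"},
    )
    world.validate()
    return world
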