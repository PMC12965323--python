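"""Flow accumulation, neighborhoods and priority water allocation."""

import numpy as np
import pytest

from multicrop import (
    AllocationRequest,
    RiverNetwork,
    allocate,
    neighborhood,
    rank_expansion_cells,
    route_discharge,
    sort_requests,
)
from multicrop.errors import NetworkError, RequestOrderError
from multicrop.scenarios import ref_mc_share

import _oracles


def _net(downstream, runoff, basin=None):
    n = len(downstream)
    basin = [0] * n if basin is None else basin
    return RiverNetwork(downstream, basin, runoff)


def test_route_three_cell_chain():
    net = _net([1, 2, -1], [1.0, 1.0, 1.0])
    assert route_discharge(net).tolist() == [1.0, 2.0, 3.0]


def test_route_star_into_outlet():
    net = _net([3, 3, 3, -1], [2.0, 2.0, 2.0, 0.0])
    assert route_discharge(net).tolist() == [2.0, 2.0, 2.0, 6.0]


def test_route_rejects_cycle():
    with pytest.raises(NetworkError):
        _net([1, 0], [1.0, 1.0])


def test_route_matches_recursive_oracle():
    rng = np.random.default_rng(11)
    n = 50
    downstream = np.full(n, -1)
    for i in range(1, n):
        downstream[i] = rng.integers(0, i)
    runoff = rng.uniform(0, 5, n)
    net = _net(downstream.tolist(), runoff)
    assert np.allclose(
        route_discharge(net), _oracles.naive_discharge(downstream, runoff), rtol=1e-12
    )


def test_neighborhood_geometry():
    # two cells ~111 km apart along a meridian
    lat = np.array([0.0, 1.0])
    lon = np.array([0.0, 0.0])
    basin = np.array([0, 0])
    assert neighborhood(0, lat, lon, basin, radius_km=1e-6).tolist() == [0]
    assert neighborhood(0, lat, lon, basin, radius_km=100.0).tolist() == [0]
    assert neighborhood(0, lat, lon, basin, radius_km=120.0).tolist() == [0, 1]


def test_neighborhood_monotone_in_radius_and_basin_bound(world_small):
    basin = world_small.basin_id
    prev = None
    for radius in (25.0, 50.0, 100.0, 200.0):
        hood = set(
            neighborhood(0, world_small.lat, world_small.lon, basin, radius).tolist()
        )
        assert 0 in hood
        assert all(basin[c] == basin[0] for c in hood)
        if prev is not None:
            assert hood >= prev
        prev = hood


def test_return_flow_keeps_downstream_served():
    # 2-cell chain: upstream expansion (withdraw 6, consume 3), then
    # downstream demand 7 against discharge 10-3=7
    net = _net([1, -1], [10.0, 0.0])
    lat = np.array([0.0, 0.2])
    lon = np.zeros(2)
    reqs = sort_requests(
        [
            AllocationRequest(0, "expansion", 6.0, 3.0, rank=2.0),
            AllocationRequest(1, "expansion", 7.0, 7.0, rank=1.0),
        ],
        net.basin_id,
    )
    res = allocate(reqs, net, lat, lon, radius_km=50.0)
    assert res.fractions.tolist() == [1.0, 1.0]
    assert res.allocated_withdrawal.tolist() == [6.0, 7.0]


def test_committed_shortfall_booked_as_groundwater():
    net = _net([-1], [2.0])
    reqs = [AllocationRequest(0, "committed", 5.0, 5.0)]
    res = allocate(reqs, net, np.zeros(1), np.zeros(1))
    assert res.fractions[0] == 1.0
    assert res.groundwater[0] == pytest.approx(3.0)
    assert res.allocated_withdrawal[0] == pytest.approx(2.0)


def test_unsorted_requests_rejected():
    net = _net([1, -1], [1.0, 1.0])
    reqs = [
        AllocationRequest(0, "expansion", 1.0, 1.0),
        AllocationRequest(1, "non_ag", 1.0, 1.0),
    ]
    with pytest.raises(RequestOrderError):
        allocate(reqs, net, np.zeros(2), np.zeros(2))


def _random_case(rng, n_max=10):
    n = int(rng.integers(2, n_max + 1))
    downstream = np.full(n, -1)
    for i in range(1, n):
        downstream[i] = rng.integers(0, i)
    runoff = rng.uniform(0, 3, n) * (rng.random(n) > 0.2)
    lat = rng.uniform(-30, 30) + rng.uniform(-1.0, 1.0, n)
    lon = rng.uniform(-170, 170) + rng.uniform(-1.0, 1.0, n)
    basin = np.zeros(n, dtype=int)
    reqs = []
    for _ in range(int(rng.integers(1, 8))):
        cell = int(rng.integers(n))
        purpose = ("non_ag", "committed", "expansion")[int(rng.integers(3))]
        w = float(rng.exponential(2.0))
        c = float(rng.uniform(0.2, 1.0) * w)
        reqs.append(
            AllocationRequest(cell, purpose, w, c, rank=float(rng.uniform(0, 10)))
        )
    return _net(downstream.tolist(), runoff, basin.tolist()), lat, lon, sort_requests(
        reqs, basin
    )


@pytest.mark.parametrize("seed", range(30))
def test_allocation_matches_bruteforce_simulator(seed):
    rng = np.random.default_rng(seed)
    net, lat, lon, reqs = _random_case(rng)
    res = allocate(reqs, net, lat, lon, radius_km=150.0)
    frac, gw, avail = _oracles.naive_allocate(
        reqs, net.downstream, net.basin_id, net.runoff, lat, lon, 150.0
    )
    assert np.allclose(res.fractions, frac, atol=1e-9)
    for c in range(net.n):
        assert res.groundwater[c] == pytest.approx(gw.get(c, 0.0), abs=1e-9)
    assert np.allclose(res.available, avail, atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_no_negative_availability_and_outlet_mass_balance(seed):
    rng = np.random.default_rng(100 + seed)
    net, lat, lon, reqs = _random_case(rng)
    res = allocate(reqs, net, lat, lon, radius_km=150.0)
    assert (res.available >= -1e-12).all()
    # outlet balance: natural discharge minus consumption taken upstream
    # minus full withdrawals taken at the outlet itself
    outlet = int(np.where(net.downstream == -1)[0][0])
    removed = 0.0
    for (ridx, source, take) in res.log:
        req = reqs[ridx]
        rho = req.consumption / req.withdrawal
        if source == outlet:
            removed += take
        else:
            removed += take * rho  # outlet is downstream of every other cell
    assert res.available[outlet] == pytest.approx(
        res.natural[outlet] - removed, rel=1e-9, abs=1e-12
    )


def test_adding_runoff_never_reduces_fulfillment():
    rng = np.random.default_rng(5)
    for _ in range(10):
        net, lat, lon, reqs = _random_case(rng)
        res1 = allocate(reqs, net, lat, lon, radius_km=150.0)
        boosted = RiverNetwork(net.downstream, net.basin_id, net.runoff + 1.0)
        res2 = allocate(reqs, boosted, lat, lon, radius_km=150.0)
        exp = [i for i, r in enumerate(reqs) if r.purpose == "expansion"]
        assert (res2.fractions[exp] >= res1.fractions[exp] - 1e-9).all()


def test_nonag_priority_starves_expansion():
    net = _net([1, 2, -1], [2.0, 2.0, 2.0])
    lat = np.array([0.0, 0.2, 0.4])
    lon = np.zeros(3)
    reqs = sort_requests(
        [
            AllocationRequest(1, "non_ag", 6.0, 6.0),  # the entire basin yield
            AllocationRequest(0, "expansion", 3.0, 3.0, rank=1.0),
            AllocationRequest(2, "expansion", 3.0, 3.0, rank=0.5),
        ],
        net.basin_id,
    )
    res = allocate(reqs, net, lat, lon, radius_km=80.0)
    by_purpose = {r.purpose: f for r, f in zip(reqs, res.fractions)}
    assert by_purpose["non_ag"] == 1.0
    exp_fracs = [f for r, f in zip(reqs, res.fractions) if r.purpose == "expansion"]
    assert all(f == 0.0 for f in exp_fracs)


def test_unlimited_runoff_serves_every_expansion():
    rng = np.random.default_rng(9)
    net, lat, lon, reqs = _random_case(rng)
    flooded = RiverNetwork(net.downstream, net.basin_id, net.runoff + 1e9)
    res = allocate(reqs, flooded, lat, lon, radius_km=150.0)
    assert (res.fractions == 1.0).all()
    assert (res.groundwater == 0.0).all()


def test_expansion_rank_key_properties(world_small, pipeline_small):
    ytable = pipeline_small["yields"]
    share = ref_mc_share(world_small)
    rank = rank_expansion_cells(world_small, ytable, share)
    # loop oracle
    for i in world_small.cell_ids[:20]:
        total = 0.0
        for crop in world_small.crop_names:
            area = float(
                world_small.crops["physical_area"].sel(cell=i, crop=crop).sum()
            )
            y_mc_irr = float(
                ytable["y_annual_mc"].sel(cell=i, crop=crop, regime="irrigated")
            )
            s_rf = float(share.sel(cell=i, crop=crop, regime="rainfed"))
            y_ref_rf = float(
                ytable["y_main"].sel(cell=i, crop=crop, regime="rainfed")
            ) + s_rf * float(ytable["y_off"].sel(cell=i, crop=crop, regime="rainfed"))
            total += area * (y_mc_irr - y_ref_rf)
        assert rank[i] == pytest.approx(total, rel=1e-9)
    # zero cropland -> zero key; doubling the yield gap doubles the key
    import dataclasses
    import xarray as xr

    zeroed = world_small.crops.copy()
    zeroed["physical_area"] = xr.zeros_like(world_small.crops["physical_area"])
    zeroed["harvested_area"] = xr.zeros_like(world_small.crops["harvested_area"])
    w0 = dataclasses.replace(world_small, crops=zeroed)
    assert (rank_expansion_cells(w0, ytable, ref_mc_share(w0)) == 0.0).all()

    doubled = ytable.copy()
    for var in doubled.data_vars:
        doubled[var] = ytable[var] * 2.0
    assert np.allclose(
        rank_expansion_cells(world_small, doubled, share), 2.0 * rank, rtol=1e-12
    )
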