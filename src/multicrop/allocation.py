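"""River routing and priority water allocation with upstream-downstream accounting.

Runoff is accumulated into natural discharge along the downstream-pointer
forest in topological order.  Demands are then served in strict priority
order — non-agricultural uses first, then committed irrigation (demand of
already-irrigated areas), then irrigation expansion ranked by the yield
gain irrigation brings — basin by basin.

A request at cell c may withdraw from any cell of the same basin whose
center lies within a radius (default 100 km), tapped nearest-first.
Withdrawing w at source s with consumption ratio rho = consumption /
withdrawal removes w from s's available discharge and rho*w from every
cell strictly downstream of s: the return flow w - rho*w re-enters at
s's downstream neighbor and remains withdrawable there.  A request may
therefore take at most min(avail[s], min_downstream_avail / rho) from s,
which keeps every cell's availability nonnegative.

Non-agricultural and committed shortfalls are booked as non-renewable
groundwater (they are always fulfilled); expansion gets no groundwater
and is satisfied only up to a fulfilled fraction in [0, 1], by which the
expansion area is later scaled proportionally across crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import NetworkError, RequestOrderError
from .world import World

EARTH_RADIUS_KM = 6371.0

#: priority classes in service order
PRIORITY = {"non_ag": 0, "committed": 1, "expansion": 2}


class RiverNetwork:
    """Downstream-pointer forest with basin labels and annual runoff."""

    def __init__(self, downstream, basin_id, runoff):
        self.downstream = np.asarray(downstream, dtype=int)
        self.basin_id = np.asarray(basin_id, dtype=int)
        self.runoff = np.asarray(runoff, dtype=float)
        n = len(self.downstream)
        if len(self.basin_id) != n or len(self.runoff) != n:
            raise NetworkError("downstream, basin_id and runoff must be equal length")
        if (self.runoff < 0).any():
            raise NetworkError("runoff must be >= 0")
        self.n = n
        self.topo_order = self._toposort()
        # strict downstream chain per cell, nearest first
        self.chains: list[np.ndarray] = []
        for c in range(n):
            chain = []
            d = self.downstream[c]
            while d != -1:
                chain.append(d)
                d = self.downstream[d]
            self.chains.append(np.array(chain, dtype=int))

    @classmethod
    def from_world(cls, world: World) -> "RiverNetwork":
        return cls(world.downstream, world.basin_id, world.runoff)

    def _toposort(self) -> np.ndarray:
        indeg = np.zeros(self.n, dtype=int)
        for c in range(self.n):
            d = self.downstream[c]
            if d == -1:
                continue
            if not 0 <= d < self.n:
                raise NetworkError(f"downstream[{c}]={d} outside the grid")
            indeg[d] += 1
        order = []
        stack = [c for c in range(self.n) if indeg[c] == 0]
        while stack:
            c = stack.pop()
            order.append(c)
            d = self.downstream[c]
            if d != -1:
                indeg[d] -= 1
                if indeg[d] == 0:
                    stack.append(d)
        if len(order) != self.n:
            raise NetworkError("cycle detected in river network")
        return np.array(order, dtype=int)


def route_discharge(network: RiverNetwork) -> np.ndarray:
    """Natural discharge per cell: own runoff plus all upstream runoff (km^3/yr)."""
    discharge = network.runoff.copy()
    for c in network.topo_order:
        d = network.downstream[c]
        if d != -1:
            discharge[d] += discharge[c]
    return discharge


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance between degree coordinates, in km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def neighborhood(
    cell: int,
    lat: np.ndarray,
    lon: np.ndarray,
    basin_id: np.ndarray,
    radius_km: float = 100.0,
) -> np.ndarray:
    """Cells of the same basin within *radius_km* of *cell*, nearest-first.

    Always contains the cell itself (distance 0); ties are broken by
    cell_id.  Water may not be moved across basin boundaries.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    dist = haversine_km(lat[cell], lon[cell], lat, lon)
    ok = (dist <= radius_km) & (basin_id == basin_id[cell])
    idx = np.nonzero(ok)[0]
    order = np.lexsort((idx, dist[idx]))
    return idx[order]


@dataclass(frozen=True)
class AllocationRequest:
    cell: int
    purpose: str  # non_ag | committed | expansion
    withdrawal: float  # km^3/yr demanded
    consumption: float  # km^3/yr demanded, <= withdrawal
    rank: float = 0.0  # expansion rank key (higher served first)

    def __post_init__(self):
        if self.purpose not in PRIORITY:
            raise ValueError(f"unknown purpose {self.purpose!r}")
        if self.consumption > self.withdrawal * (1 + 1e-12) or self.consumption < 0:
            raise ValueError("need 0 <= consumption <= withdrawal")


@dataclass
class AllocationResult:
    fractions: np.ndarray  # fulfilled fraction per request
    groundwater: np.ndarray  # km^3/yr per cell (non_ag/committed shortfall)
    available: np.ndarray  # final available discharge per cell
    natural: np.ndarray  # natural discharge per cell
    allocated_withdrawal: np.ndarray  # per request
    allocated_consumption: np.ndarray  # per request
    log: list = field(default_factory=list)  # (request idx, source cell, withdrawal)


def sort_requests(requests, basin_id) -> list[AllocationRequest]:
    """Deterministic service order: basin, then priority class, then rank
    (descending, expansion only), then cell_id."""
    return sorted(
        requests,
        key=lambda r: (basin_id[r.cell], PRIORITY[r.purpose], -r.rank, r.cell),
    )


def _check_order(requests, basin_id) -> None:
    last = None
    for r in requests:
        key = (basin_id[r.cell], PRIORITY[r.purpose], -r.rank, r.cell)
        if last is not None and key < last:
            raise RequestOrderError(
                "requests must be sorted by basin, priority class and rank "
                "(use sort_requests)"
            )
        last = key


def allocate(
    requests: list[AllocationRequest],
    network: RiverNetwork,
    lat: np.ndarray,
    lon: np.ndarray,
    radius_km: float = 100.0,
    discharge: np.ndarray | None = None,
) -> AllocationResult:
    """Serve *requests* (pre-sorted) from the river network's discharge."""
    _check_order(requests, network.basin_id)
    natural = route_discharge(network) if discharge is None else discharge.copy()
    avail = natural.copy()
    groundwater = np.zeros(network.n)
    fractions = np.ones(len(requests))
    alloc_w = np.zeros(len(requests))
    alloc_c = np.zeros(len(requests))
    logbook: list = []
    hood_cache: dict[int, np.ndarray] = {}
    eps = 1e-15

    for i, req in enumerate(requests):
        demand_w = req.withdrawal
        if demand_w <= 0:
            continue
        rho = req.consumption / demand_w
        if req.cell not in hood_cache:
            hood_cache[req.cell] = neighborhood(
                req.cell, lat, lon, network.basin_id, radius_km
            )
        remaining = demand_w
        got = 0.0
        for s in hood_cache[req.cell]:
            if remaining <= 0:
                break
            cap = avail[s]
            chain = network.chains[s]
            if rho > 0 and len(chain):
                cap = min(cap, avail[chain].min() / rho)
            take = min(cap, remaining)
            if take <= eps * max(demand_w, 1.0):
                continue
            avail[s] -= take
            if rho > 0 and len(chain):
                avail[chain] -= take * rho
            got += take
            remaining -= take
            logbook.append((i, int(s), float(take)))
        if (avail < -1e-9 * max(natural.max(), 1.0)).any():
            raise AssertionError("internal consistency: negative availability")
        np.clip(avail, 0.0, None, out=avail)
        alloc_w[i] = got
        alloc_c[i] = got * rho
        if remaining > eps * max(demand_w, 1.0):
            if req.purpose in ("non_ag", "committed"):
                groundwater[req.cell] += remaining
                fractions[i] = 1.0  # shortfall covered by groundwater
            else:
                fractions[i] = got / demand_w
        else:
            fractions[i] = 1.0

    return AllocationResult(
        fractions=fractions,
        groundwater=groundwater,
        available=avail,
        natural=natural,
        allocated_withdrawal=alloc_w,
        allocated_consumption=alloc_c,
        log=logbook,
    )


def rank_expansion_cells(
    world: World, yield_table: xr.Dataset, ref_mc_share: xr.DataArray
) -> np.ndarray:
    """Expansion rank key per cell: total yield gain through irrigation.

    Sum over crops of crop physical area (both regimes) times the gap
    between the annual irrigated multiple-cropping yield and the annual
    rainfed yield under the reference cropping system (main-season yield
    plus the reference multiple-cropped share of the off-season yield),
    in t DM per cell.  Higher keys are served first.
    """
    area = world.crops["physical_area"].sum(dim="regime")
    y_irr_mc = yield_table["y_annual_mc"].sel(regime="irrigated", drop=True)
    y_rf_main = yield_table["y_main"].sel(regime="rainfed", drop=True)
    y_rf_off = yield_table["y_off"].sel(regime="rainfed", drop=True)
    s_rf = ref_mc_share.sel(regime="rainfed", drop=True)
    y_rf_ref = y_rf_main + s_rf * y_rf_off
    gain = (area * (y_irr_mc - y_rf_ref)).sum(dim="crop")
    return gain.values
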