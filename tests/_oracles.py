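"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: recursion and per-cell walks
instead of topological sweeps, the spherical law of cosines instead of
the haversine formula, plain python loops instead of vectorized numpy.
"""

from __future__ import annotations

import math
from collections import defaultdict


def spherical_distance_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return 6371.0 * math.acos(min(1.0, max(-1.0, c)))


def naive_discharge(downstream, runoff) -> list[float]:
    """Discharge by direct recursion over upstream neighbours."""
    n = len(runoff)

    def disch(c, seen=()):
        assert c not in seen, "cycle"
        return runoff[c] + sum(
            disch(u, seen + (c,)) for u in range(n) if downstream[u] == c
        )

    return [disch(c) for c in range(n)]


def naive_downstream_cells(downstream, c) -> list[int]:
    out = []
    d = downstream[c]
    while d != -1:
        out.append(d)
        d = downstream[d]
    return out


def naive_allocate(requests, downstream, basin_id, runoff, lat, lon, radius_km):
    """Step-by-step sequential simulator applying the allocation rules.

    Returns (fractions, groundwater dict, available list).
    """
    avail = naive_discharge(downstream, runoff)
    n = len(avail)
    fractions = []
    groundwater: dict[int, float] = defaultdict(float)
    for req in requests:
        w = req.withdrawal
        if w <= 0:
            fractions.append(1.0)
            continue
        rho = req.consumption / w
        sources = [
            s
            for s in range(n)
            if basin_id[s] == basin_id[req.cell]
            and spherical_distance_km(lat[req.cell], lon[req.cell], lat[s], lon[s])
            <= radius_km
        ]
        sources.sort(
            key=lambda s: (
                spherical_distance_km(lat[req.cell], lon[req.cell], lat[s], lon[s]),
                s,
            )
        )
        remaining = w
        got = 0.0
        for s in sources:
            if remaining <= 0:
                break
            ds = naive_downstream_cells(downstream, s)
            cap = avail[s]
            if rho > 0 and ds:
                cap = min(cap, min(avail[d] for d in ds) / rho)
            take = min(cap, remaining)
            if take <= 0:
                continue
            avail[s] -= take
            for d in ds:
                avail[d] -= take * rho
            got += take
            remaining -= take
        if remaining > 1e-12 * max(w, 1.0):
            if req.purpose in ("non_ag", "committed"):
                groundwater[req.cell] += remaining
                fractions.append(1.0)
            else:
                fractions.append(got / w)
        else:
            fractions.append(1.0)
    return fractions, groundwater, avail
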