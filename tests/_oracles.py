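"""Independent brute-force reference implementations.

Every function here recomputes a pipeline quantity with plain loops and
first-principles formulas, deliberately sharing no code with the package,
so tests can compare the optimised implementations against them.
"""

from __future__ import annotations

import math


def dist(a, b, p: float = 2.0) -> float:
    return (abs(a[0] - b[0]) ** p + abs(a[1] - b[1]) ** p) ** (1.0 / p)


def nearest_facility(unit_xy, fac_xy: dict, p: float = 2.0) -> str:
    """Id of the nearest facility; ties broken to the lowest id."""
    return min(sorted(fac_xy), key=lambda f: (dist(unit_xy, fac_xy[f], p), f))


def voronoi_assignment(units: dict, fac_xy: dict) -> dict:
    """unit id -> facility id under Euclidean nearest-point assignment."""
    return {u: nearest_facility(xy, fac_xy) for u, xy in units.items()}


def pressure(units_xy: dict, needy: dict, fac_xy: dict, capacity: dict) -> dict:
    assigned = {f: 0.0 for f in fac_xy}
    for u, f in voronoi_assignment(units_xy, fac_xy).items():
        assigned[f] += needy[u]
    return {f: assigned[f] / capacity[f] for f in fac_xy}


def di(units_xy: dict, fac_xy: dict, p: float = 2.0) -> float:
    """Max over units of the distance to the nearest facility."""
    return max(
        min(dist(xy, fxy, p) for fxy in fac_xy.values())
        for xy in units_xy.values()
    )


def zap(unit_xy, radius: float, fac_xy: dict, p: float = 2.0) -> set:
    return {f for f, fxy in fac_xy.items() if dist(unit_xy, fxy, p) <= radius}


def dap(unit_xy, zap_ids, fac_xy: dict, pressures: dict, p: float = 2.0) -> float:
    ds = [dist(unit_xy, fac_xy[f], p) for f in zap_ids]
    ws = [pressures[f] for f in zap_ids]
    if sum(ws) == 0:
        return sum(ds) / len(ds)
    return sum(w * d for w, d in zip(ws, ds)) / sum(ws)


def standardize(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in values]


def combine(z_by_cat: dict, weights: dict, unit_ids) -> list:
    return [
        sum(weights[c] * z_by_cat[c][u] for c in weights) for u in unit_ids
    ]


def quantile_type7(sorted_values, q: float) -> float:
    n = len(sorted_values)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_values[lo] + (h - lo) * (sorted_values[hi] - sorted_values[lo])


def deciles(values) -> list:
    s = sorted(values)
    bounds = [quantile_type7(s, k / 10.0) for k in range(1, 10)]
    return [1 + sum(v > b for b in bounds) for v in values]


def idw(sample_xy: list, sample_values: list, query_xy, k: int, power: float) -> float:
    order = sorted(
        range(len(sample_xy)), key=lambda i: dist(sample_xy[i], query_xy)
    )[: min(k, len(sample_xy))]
    d0 = dist(sample_xy[order[0]], query_xy)
    if d0 == 0:
        return sample_values[order[0]]
    num = sum(sample_values[i] * dist(sample_xy[i], query_xy) ** (-power) for i in order)
    den = sum(dist(sample_xy[i], query_xy) ** (-power) for i in order)
    return num / den


def single_linkage_clusters(points: list, tol: float) -> int:
    """Number of clusters under single-linkage merging at radius tol."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist(points[i], points[j]) <= tol:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})
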