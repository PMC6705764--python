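"""Availability: Voronoi areas of influence and theoretical pressure rates.

Each facility's area of influence is its Voronoi cell: the set of points
closer to it than to any other facility of the same category.  The needy
population of every residential unit is assigned entirely to the facility
whose cell contains it — realised here as nearest-facility assignment,
which is mathematically the same thing without polygon geometry.  The
theoretical pressure rate on a facility is then

    pressure = assigned needy population / professional count (capacity).

Assignment is referenced to the population scope of the category's range:
units only compete for facilities of their own EPCI (primary equipment) or
region (tertiary equipment).  A scope with units but no facility is flagged
and its units fall back to the globally nearest facility.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geodata import Facility, ResidentialUnit

logger = logging.getLogger(__name__)


def merge_colocated(facilities: Sequence[Facility], tol: float = 0.0) -> list[Facility]:
    """Merge same-category facilities within ``tol`` map units of each other.

    Facilities sharing a site have identical areas of influence, so they are
    collapsed into one site whose capacity is the sum of the parts; the
    merged id concatenates the sorted member ids.  Merging is single-linkage:
    any chain of pairwise-within-``tol`` facilities becomes one site.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    out: list[Facility] = []
    by_cat: dict[str, list[Facility]] = {}
    for f in facilities:
        by_cat.setdefault(f.category, []).append(f)
    for cat in sorted(by_cat):
        group = sorted(by_cat[cat], key=lambda f: f.id)
        xy = np.array([[f.x, f.y] for f in group])
        pairs = cKDTree(xy).query_pairs(r=tol, output_type="ndarray")
        n = len(group)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
            n_comp, labels = connected_components(adj, directed=False)
        else:
            n_comp, labels = n, np.arange(n)
        for comp in range(n_comp):
            members = [group[i] for i in np.flatnonzero(labels == comp)]
            if len(members) == 1:
                out.append(members[0])
                continue
            cap = sum(f.capacity for f in members)
            # capacity-weighted site location (members are within tol anyway)
            x = sum(f.x * f.capacity for f in members) / cap
            y = sum(f.y * f.capacity for f in members) / cap
            out.append(
                Facility(
                    id="+".join(sorted(f.id for f in members)),
                    x=x,
                    y=y,
                    category=cat,
                    capacity=cap,
                    epci_id=members[0].epci_id,
                    region_id=members[0].region_id,
                )
            )
    out.sort(key=lambda f: (f.category, f.id))
    if len(out) < len(facilities):
        logger.info("merged %d co-located facilities into %d sites",
                    len(facilities), len(out))
    return out


def infer_facility_scopes(
    facilities: Sequence[Facility], units: Sequence[ResidentialUnit]
) -> list[Facility]:
    """Fill missing EPCI/region membership from the nearest residential unit."""
    missing = [f for f in facilities if f.epci_id is None or f.region_id is None]
    if not missing:
        return list(facilities)
    tree = cKDTree(np.array([[u.x, u.y] for u in units]))
    out = []
    for f in facilities:
        if f.epci_id is None or f.region_id is None:
            _, i = tree.query([f.x, f.y])
            u = units[int(i)]
            f = replace(
                f,
                epci_id=f.epci_id or u.epci_id,
                region_id=f.region_id or u.region_id,
            )
        out.append(f)
    return out


def nearest_assignment(
    unit_xy: np.ndarray, fac_xy: np.ndarray, fac_ids: Sequence[str]
) -> np.ndarray:
    """Index of the Euclidean-nearest facility per unit.

    Ties break to the lowest facility id (columns are scanned in sorted-id
    order, argmin keeps the first minimum).
    """
    order = np.argsort(np.asarray(fac_ids, dtype=object))
    d = cdist(unit_xy, np.asarray(fac_xy, dtype=float)[order])
    return order[np.argmin(d, axis=1)]


def assign_population(
    facilities: Sequence[Facility],
    units: Sequence[ResidentialUnit],
    needy_selector: str = "all",
    reference_scope: str = "epci",
    pressure_normalization: str = "none",
) -> pd.DataFrame:
    """Voronoi assignment of needy population and pressure per facility.

    Returns a PressureTable: a DataFrame indexed by facility id with columns
    ``category``, ``assigned_population``, ``capacity``, ``pressure``.
    With ``pressure_normalization='scope_share'`` the pressure is divided by
    the scope's total needy population (an alternative reading of
    scope-referenced pressure); the default leaves population-per-
    professional untouched.
    """
    if not facilities:
        raise ValueError("no facilities to assign population to")
    if reference_scope not in ("epci", "region"):
        raise ValueError(f"reference_scope must be epci|region, got {reference_scope!r}")
    if pressure_normalization not in ("none", "scope_share"):
        raise ValueError(f"unknown pressure_normalization {pressure_normalization!r}")

    scope_attr = f"{reference_scope}_id"
    facilities = infer_facility_scopes(facilities, units)
    categories = sorted({f.category for f in facilities})
    if len(categories) != 1:
        raise ValueError(
            f"assign_population handles one category at a time, got {categories}"
        )

    fac_scope = np.array([getattr(f, scope_attr) for f in facilities], dtype=object)
    fac_ids = [f.id for f in facilities]
    fac_xy = np.array([[f.x, f.y] for f in facilities])
    needy = np.array([u.needy(needy_selector) for u in units])
    unit_xy = np.array([[u.x, u.y] for u in units])
    unit_scope = np.array([getattr(u, scope_attr) for u in units], dtype=object)

    assigned = np.zeros(len(facilities))
    scope_totals: dict[str, float] = {}
    for scope in sorted(set(unit_scope)):
        in_scope = unit_scope == scope
        scope_totals[scope] = float(needy[in_scope].sum())
        fac_mask = fac_scope == scope
        if not fac_mask.any():
            logger.warning(
                "scope %s=%r has %d units but no %r facility; assigning to the "
                "globally nearest facility (unserved in scope)",
                reference_scope, scope, int(in_scope.sum()), categories[0],
            )
            fac_mask = np.ones(len(facilities), dtype=bool)
        cand = np.flatnonzero(fac_mask)
        nearest = nearest_assignment(
            unit_xy[in_scope], fac_xy[cand], [fac_ids[i] for i in cand]
        )
        np.add.at(assigned, cand[nearest], needy[in_scope])

    caps = np.array([f.capacity for f in facilities], dtype=float)
    pressure = assigned / caps
    if pressure_normalization == "scope_share":
        denom = np.array(
            [max(scope_totals.get(s, 0.0), 1e-300) for s in fac_scope]
        )
        pressure = pressure / denom

    table = pd.DataFrame(
        {
            "category": categories[0],
            "assigned_population": assigned,
            "capacity": caps,
            "pressure": pressure,
            "scope": fac_scope,
        },
        index=pd.Index(fac_ids, name="facility_id"),
    )
    return table


def pressure_tables(
    facilities: Sequence[Facility],
    units: Sequence[ResidentialUnit],
    configs,
    pressure_normalization: str = "none",
    merge_tol: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Pressure table per category, after co-located merging."""
    merged = merge_colocated(facilities, tol=merge_tol)
    out = {}
    for cfg in configs:
        fac_c = [f for f in merged if f.category == cfg.name]
        if not fac_c:
            raise ValueError(f"no facilities for category {cfg.name!r}")
        out[cfg.name] = assign_population(
            fac_c,
            units,
            needy_selector=cfg.needy_selector,
            reference_scope=cfg.reference_scope,
            pressure_normalization=pressure_normalization,
        )
    return out
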