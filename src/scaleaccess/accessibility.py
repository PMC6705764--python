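"""Potential accessibility distances (the demand side of the index).

For one equipment category the computation runs per IRIS and per
residential unit:

1. DI — the search radius of an IRIS: the largest, over its residential
   units, of the distance from a unit to its nearest facility.  By
   construction every unit of the IRIS can reach at least one facility
   within DI.
2. ZAP — the potential accessibility area of a unit: the disc of radius DI
   around it; operationally, the set of facilities at distance <= DI
   (boundary inclusive).
3. DAP — the potential accessibility distance: the mean of the distances to
   the ZAP facilities, weighted by the theoretical pressure each facility
   experiences, so congested supply pulls the expected travel distance
   toward itself.

DI is Euclidean by default even when DAP distances come from another
provider (``di_metric='provider'`` switches the radius to the same metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceProvider, EuclideanProvider
from .geodata import Facility, ResidentialUnit

logger = logging.getLogger(__name__)


@dataclass
class CatchmentResult:
    """Per-category catchment quantities: DI per IRIS, ZAP and DAP per unit."""

    category: str
    di: dict[str, float]                 # iris_id -> radius
    zap: dict[str, tuple[str, ...]]      # unit_id -> facility ids
    dap: pd.Series                       # unit_id -> distance


def _pairwise(provider, units: Sequence[ResidentialUnit],
              facilities: Sequence[Facility]) -> np.ndarray:
    u_xy = np.array([[u.x, u.y] for u in units], dtype=float)
    f_xy = np.array([[f.x, f.y] for f in facilities], dtype=float)
    return provider.pairwise(
        u_xy, f_xy, [u.id for u in units], [f.id for f in facilities]
    )


def compute_di(
    units_of_iris: Sequence[ResidentialUnit],
    facilities: Sequence[Facility],
    provider: DistanceProvider | None = None,
) -> float:
    """Search radius of an IRIS: max over units of the nearest-facility distance."""
    if not units_of_iris:
        raise ValueError("IRIS has no residential units")
    if not facilities:
        raise ValueError("no facilities for category: DI undefined")
    provider = provider or EuclideanProvider()
    d = _pairwise(provider, units_of_iris, facilities)
    return float(d.min(axis=1).max())


def select_zap(
    unit: ResidentialUnit,
    di: float,
    facilities: Sequence[Facility],
    provider: DistanceProvider | None = None,
) -> tuple[str, ...]:
    """Facilities within the unit's potential accessibility area (d <= DI)."""
    provider = provider or EuclideanProvider()
    d = _pairwise(provider, [unit], facilities)[0]
    ids = tuple(f.id for f, di_f in zip(facilities, d) if di_f <= di)
    return ids


def compute_dap(
    unit: ResidentialUnit,
    zap: Sequence[str],
    pressures: Mapping[str, float] | pd.DataFrame,
    facilities: Sequence[Facility],
    provider: DistanceProvider | None = None,
    pressure_weighting: str = "pressure",
) -> float:
    """Pressure-weighted mean distance to the ZAP facilities."""
    if not zap:
        raise ValueError(f"unit {unit.id!r}: empty ZAP")
    provider = provider or EuclideanProvider()
    fac_by_id = {f.id: f for f in facilities}
    zap_fac = [fac_by_id[i] for i in zap]
    d = _pairwise(provider, [unit], zap_fac)[0]
    if isinstance(pressures, pd.DataFrame):
        p = pressures.loc[list(zap), "pressure"].to_numpy(dtype=float)
    else:
        p = np.array([pressures[i] for i in zap], dtype=float)
    return float(_weighted_dap(d, p, pressure_weighting))


def _weighted_dap(d: np.ndarray, p: np.ndarray, pressure_weighting: str) -> float:
    if pressure_weighting == "inverse_pressure":
        with np.errstate(divide="ignore"):
            w = np.where(p > 0, 1.0 / np.where(p > 0, p, 1.0), 0.0)
    elif pressure_weighting == "pressure":
        w = p
    else:
        raise ValueError(f"unknown pressure_weighting {pressure_weighting!r}")
    tot = w.sum()
    if tot <= 0:
        # all-zero weights (e.g. every ZAP facility unloaded): plain mean
        return float(d.mean())
    return float((w * d).sum() / tot)


def category_surface(
    units: Sequence[ResidentialUnit],
    facilities: Sequence[Facility],
    pressures: pd.DataFrame,
    provider: DistanceProvider | None = None,
    category: str | None = None,
    di_metric: str = "euclidean",
    pressure_weighting: str = "pressure",
) -> CatchmentResult:
    """DI -> ZAP -> DAP for every residential unit, one category.

    ``pressures`` is the category's PressureTable (indexed by facility id).
    """
    provider = provider or EuclideanProvider()
    if di_metric not in ("euclidean", "provider"):
        raise ValueError(f"di_metric must be euclidean|provider, got {di_metric!r}")
    if category is not None:
        facilities = [f for f in facilities if f.category == category]
    else:
        cats = {f.category for f in facilities}
        if len(cats) != 1:
            raise ValueError(f"facilities span several categories: {sorted(cats)}")
        category = next(iter(cats))
    if not facilities:
        raise ValueError(f"no facilities for category {category!r}")

    di_provider = EuclideanProvider() if di_metric == "euclidean" else provider

    d_prov = _pairwise(provider, units, facilities)
    d_di = (
        d_prov
        if di_metric == "provider" or provider.kind == "euclidean"
        else _pairwise(di_provider, units, facilities)
    )

    iris_of = np.array([u.iris_id for u in units], dtype=object)
    nearest_di = d_di.min(axis=1)
    di: dict[str, float] = {}
    for iris in sorted(set(iris_of)):
        di[iris] = float(nearest_di[iris_of == iris].max())
    logger.info(
        "category %s: DI over %d IRIS, range [%.1f, %.1f]",
        category, len(di), min(di.values()), max(di.values()),
    )

    p = pressures.loc[[f.id for f in facilities], "pressure"].to_numpy(dtype=float)
    fac_ids = np.array([f.id for f in facilities], dtype=object)
    zap: dict[str, tuple[str, ...]] = {}
    dap = np.empty(len(units))
    for i, u in enumerate(units):
        radius = di[u.iris_id]
        mask = d_di[i] <= radius
        if not mask.any():
            # DI is built over this IRIS's units, so its own nearest facility
            # is always within DI; unreachable unless DI came from elsewhere
            raise RuntimeError(f"unit {u.id!r}: empty ZAP at DI={radius}")
        zap[u.id] = tuple(fac_ids[mask])
        dap[i] = _weighted_dap(d_prov[i][mask], p[mask], pressure_weighting)
    return CatchmentResult(
        category=category,
        di=di,
        zap=zap,
        dap=pd.Series(dap, index=pd.Index([u.id for u in units], name="unit_id"),
                      name=f"dap_{category}"),
    )
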