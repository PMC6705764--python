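"""Pluggable distance providers.

The index is built on straight-line (Euclidean) distances by default; the
sensitivity machinery swaps in a Minkowski distance (exponent ~1.25, a
compromise between Euclidean under- and Manhattan over-estimation of road
travel) or a precomputed unit-by-facility distance matrix standing in for
road-network routing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


class DistanceLookupError(KeyError):
    """A queried (unit, facility) pair is absent from a matrix provider."""


class DistanceProvider:
    """Base class: computes unit-by-facility distance blocks.

    Subclasses implement :meth:`pairwise`; ids are only needed by the
    matrix-backed provider, coordinate providers ignore them.
    """

    kind: str = "abstract"

    def pairwise(
        self,
        a_xy: np.ndarray,
        b_xy: np.ndarray,
        a_ids: Sequence[str] | None = None,
        b_ids: Sequence[str] | None = None,
    ) -> np.ndarray:
        raise NotImplementedError

    def distance(self, a_xy, b_xy, a_id: str | None = None, b_id: str | None = None) -> float:
        a = np.atleast_2d(np.asarray(a_xy, dtype=float))
        b = np.atleast_2d(np.asarray(b_xy, dtype=float))
        ids_a = [a_id] if a_id is not None else None
        ids_b = [b_id] if b_id is not None else None
        return float(self.pairwise(a, b, ids_a, ids_b)[0, 0])


class MinkowskiProvider(DistanceProvider):
    """Minkowski distance ``(|dx|^p + |dy|^p)^(1/p)``; default p = 1.25."""

    kind = "minkowski"

    def __init__(self, p: float = 1.25):
        if p < 1:
            raise ValueError(f"Minkowski exponent must be >= 1, got {p}")
        self.p = float(p)

    def pairwise(self, a_xy, b_xy, a_ids=None, b_ids=None) -> np.ndarray:
        a = np.asarray(a_xy, dtype=float)
        b = np.asarray(b_xy, dtype=float)
        return cdist(a, b, metric="minkowski", p=self.p)

    def __repr__(self) -> str:
        return f"MinkowskiProvider(p={self.p})"


class EuclideanProvider(MinkowskiProvider):
    """Straight-line distance (the p = 2 Minkowski special case)."""

    kind = "euclidean"

    def __init__(self):
        super().__init__(p=2.0)

    def __repr__(self) -> str:
        return "EuclideanProvider()"


class MatrixProvider(DistanceProvider):
    """Distances looked up in a precomputed (unit, facility) table.

    Stands in for road-network distances; the table must be complete for
    every queried pair.
    """

    kind = "matrix"

    def __init__(self, entries: dict[tuple[str, str], float]):
        self.entries = {
            (str(a), str(b)): float(d) for (a, b), d in entries.items()
        }
        for pair, d in self.entries.items():
            if d < 0:
                raise ValueError(f"negative distance for pair {pair}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MatrixProvider":
        """Load from CSV with columns unit_id, facility_id, distance."""
        df = pd.read_csv(path, dtype={"unit_id": str, "facility_id": str})
        entries = {
            (r.unit_id, r.facility_id): float(r.distance)
            for r in df.itertuples(index=False)
        }
        return cls(entries)

    def _lookup(self, a: str, b: str) -> float:
        # symmetric: accept either orientation
        for pair in ((a, b), (b, a)):
            if pair in self.entries:
                return self.entries[pair]
        raise DistanceLookupError(f"no distance entry for pair ({a!r}, {b!r})")

    def pairwise(self, a_xy, b_xy, a_ids=None, b_ids=None) -> np.ndarray:
        if a_ids is None or b_ids is None:
            raise DistanceLookupError(
                "matrix provider needs unit/facility ids to look up distances"
            )
        out = np.empty((len(a_ids), len(b_ids)), dtype=float)
        for i, a in enumerate(a_ids):
            for j, b in enumerate(b_ids):
                out[i, j] = self._lookup(str(a), str(b))
        return out

    def __repr__(self) -> str:
        return f"MatrixProvider({len(self.entries)} entries)"


def parse_provider(spec: str) -> DistanceProvider:
    """Parse ``euclidean`` | ``minkowski[:p]`` | ``matrix:<csv path>``."""
    if spec == "euclidean":
        return EuclideanProvider()
    if spec == "minkowski":
        return MinkowskiProvider()
    if spec.startswith("minkowski:"):
        return MinkowskiProvider(p=float(spec.split(":", 1)[1]))
    if spec.startswith("matrix:"):
        return MatrixProvider.from_csv(spec.split(":", 1)[1])
    raise ValueError(f"unknown distance provider spec {spec!r}")
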