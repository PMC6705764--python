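"""From per-category distances to the combined accessibility index.

The per-category potential accessibility distances (DAP) are skewed; each is
pushed toward normality with a fixed-exponent Box-Cox transform, zero
distances first replaced by a tiny positive constant (1e-7).  The
transformed variables are z-standardized over the whole set of residential
units in the run and combined as a weighted sum

    index_u = sum_e W_e * z_{u,e}

with W_e the equipment-frequency weights.  Low index = high accessibility.
Units are then classified into deciles (decile 10 = worst accessibility),
optionally interpolated to a regular grid with inverse-distance weighting
(12 nearest neighbours, squared-distance weights), and averaged up to
coarser administrative scales.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Replacement for zero distances ahead of the power transform.
ZERO_REPLACEMENT = 1e-7


def boxcox(dap, lam: float, zero_replacement: float = ZERO_REPLACEMENT):
    """Box-Cox transform ``(d^lam - 1)/lam`` (``ln d`` at lam = 0).

    Accepts scalars or arrays; distances equal to zero are first replaced by
    ``zero_replacement`` so the power/log is defined.  Strictly increasing
    in ``dap`` for every lam.
    """
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be > 0")
    x = np.asarray(dap, dtype=float)
    if np.any(x < 0):
        raise ValueError("Box-Cox input distances must be >= 0")
    x = np.where(x == 0, zero_replacement, x)
    if lam == 0:
        out = np.log(x)
    else:
        out = (np.power(x, lam) - 1.0) / lam
    return out if out.ndim else float(out)


def estimate_lambda(dap, zero_replacement: float = ZERO_REPLACEMENT) -> float:
    """Maximum-likelihood Box-Cox exponent for a distance sample.

    Provided for exploration only — the index uses fixed per-category
    exponents, re-estimating them on a study area would change the meaning
    of the transformed scale.
    """
    from scipy import stats

    x = np.asarray(dap, dtype=float)
    x = np.where(x == 0, zero_replacement, x)
    _, lam = stats.boxcox(x)
    return float(lam)


def standardize(values) -> np.ndarray:
    """Z-standardize with the sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standardize needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate category: zero variance")
    return (v - v.mean()) / sd


def combine(
    z_by_category: pd.DataFrame | Mapping[str, Sequence[float]],
    weights: Mapping[str, float],
) -> pd.Series | np.ndarray:
    """Weighted sum of per-category values: ``index_u = sum_e W_e z_{u,e}``."""
    if not isinstance(z_by_category, pd.DataFrame):
        z_by_category = pd.DataFrame(dict(z_by_category))
    missing = [c for c in weights if c not in z_by_category.columns]
    if missing:
        raise KeyError(f"missing category values for {missing}")
    if z_by_category[list(weights)].isna().any().any():
        bad = z_by_category[list(weights)].isna()
        unit = bad.any(axis=1).idxmax()
        cat = bad.loc[unit].idxmax()
        raise ValueError(f"missing value for unit {unit!r}, category {cat!r}")
    out = sum(
        w * z_by_category[c].astype(float) for c, w in weights.items()
    )
    out.name = "index"
    return out


def classify_deciles(index) -> tuple[np.ndarray, np.ndarray]:
    """Decile class (1..10) per unit, plus the nine decile boundaries.

    Decile 10 holds the largest index values, i.e. the worst accessibility.
    Boundaries are the 10..90% quantiles (linear interpolation); equal index
    values always land in the same decile.
    """
    v = np.asarray(index, dtype=float)
    if v.size < 10:
        raise ValueError(f"decile classification needs >= 10 values, got {v.size}")
    bounds = np.quantile(v, np.arange(1, 10) / 10.0)
    deciles = 1 + (v[:, None] > bounds[None, :]).sum(axis=1)
    return deciles.astype(int), bounds


def idw_interpolate(
    sample_xy,
    sample_values,
    query_xy,
    k: int = 12,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation over the k nearest samples.

    ``value(q) = sum_i v_i d_i^-power / sum_i d_i^-power``; a query that
    coincides with a sample returns that sample's value exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    xy = np.asarray(sample_xy, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    q = np.atleast_2d(np.asarray(query_xy, dtype=float))
    if k > len(xy):
        logger.warning("only %d samples for k=%d neighbours; using all", len(xy), k)
        k = len(xy)
    d, idx = cKDTree(xy).query(q, k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    out = np.empty(len(q))
    exact = d[:, 0] == 0.0
    out[exact] = v[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w * v[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def interpolation_grid(bounds: tuple[float, float, float, float],
                       resolution: float | None = None) -> np.ndarray:
    """Regular grid of query points over ``(xmin, ymin, xmax, ymax)``.

    Default cell size is 1/200 of the bounding-box diagonal.
    """
    xmin, ymin, xmax, ymax = bounds
    if resolution is None:
        resolution = float(np.hypot(xmax - xmin, ymax - ymin)) / 200.0
    xs = np.arange(xmin, xmax + resolution / 2, resolution)
    ys = np.arange(ymin, ymax + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def aggregate_scale(
    index: pd.Series,
    membership: Mapping[str, str] | pd.Series,
    mode: str = "mean",
    populations: pd.Series | None = None,
) -> pd.Series:
    """Average unit-level index values up to a coarser geographic unit.

    ``membership`` maps each unit id to its target unit (IRIS, municipality,
    EPCI or region).  The default is the plain arithmetic mean of member
    values; ``population_weighted_mean`` weights members by population.
    """
    if not isinstance(membership, pd.Series):
        membership = pd.Series(dict(membership))
    membership = membership.reindex(index.index)
    if membership.isna().any():
        bad = membership.index[membership.isna()].tolist()
        raise ValueError(f"units without target membership: {bad[:5]}")
    if mode == "mean":
        return index.groupby(membership).mean().rename(index.name)
    if mode == "population_weighted_mean":
        if populations is None:
            raise ValueError("population_weighted_mean requires populations")
        populations = populations.reindex(index.index).astype(float)
        num = (index * populations).groupby(membership).sum()
        den = populations.groupby(membership).sum()
        out = num / den
        # groups with zero total population fall back to the plain mean
        empty = den == 0
        if empty.any():
            out[empty] = index.groupby(membership).mean()[empty]
        return out.rename(index.name)
    raise ValueError(f"unknown aggregation mode {mode!r}")
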