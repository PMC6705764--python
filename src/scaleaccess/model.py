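"""Model/Results interface for the accessibility index.

`AccessibilityModel` holds the data (residential units, facilities, category
configuration) and the analysis options; `fit()` runs the full pipeline —
co-located merging, Voronoi pressure rates, DI/ZAP/DAP per category, Box-Cox
transform, z-standardization, weighted combination, decile classification —
and returns an `AccessibilityResults` carrying every intermediate table, a
`summary()`, scale aggregation, IDW surface interpolation and a debug plot.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import index as idx
from .accessibility import CatchmentResult, category_surface
from .distances import DistanceProvider, EuclideanProvider
from .geodata import (
    CategoryConfig,
    Facility,
    ResidentialUnit,
    category_map,
    default_category_set,
    units_frame,
    validate_hierarchy,
)
from .pressure import merge_colocated, pressure_tables

logger = logging.getLogger(__name__)

_LEVEL_ATTR = {
    "iris": "iris_id",
    "municipality": "municipality_id",
    "epci": "epci_id",
    "region": "region_id",
}


class AccessibilityModel:
    """Multi-scalar spatial accessibility index of a territory.

    Parameters
    ----------
    units, facilities
        Validated point records; every facility category must appear in
        ``categories``.
    categories
        Category configurations (default: the ten published health
        categories).  Categories without any facility in the data are
        dropped with a warning rather than failing the whole run.
    provider
        Distance provider for DAP distances (default Euclidean).
    di_metric
        ``euclidean`` (default: the catchment radius stays Euclidean even
        under alternative providers) or ``provider``.
    pressure_weighting
        ``pressure`` (default: congested facilities weigh more) or
        ``inverse_pressure``.
    pressure_normalization
        ``none`` (population per professional) or ``scope_share``.
    combine_on
        ``z`` (default: weighted sum of standardized transformed distances)
        or ``raw_dap`` (the literal weighted sum of untransformed DAPs).
    merge_tol
        Distance within which same-category facilities are merged into one
        site (metres).
    """

    def __init__(
        self,
        units: Sequence[ResidentialUnit],
        facilities: Sequence[Facility],
        categories: Sequence[CategoryConfig] | None = None,
        provider: DistanceProvider | None = None,
        *,
        di_metric: str = "euclidean",
        pressure_weighting: str = "pressure",
        pressure_normalization: str = "none",
        combine_on: str = "z",
        zero_replacement: float = idx.ZERO_REPLACEMENT,
        merge_tol: float = 0.0,
    ):
        if not units:
            raise ValueError("no residential units")
        if not facilities:
            raise ValueError("no facilities")
        if combine_on not in ("z", "raw_dap"):
            raise ValueError(f"combine_on must be z|raw_dap, got {combine_on!r}")
        validate_hierarchy(units)
        self.units = list(units)
        all_categories = categories if categories is not None else default_category_set()
        present = {f.category for f in facilities}
        unknown = present - {c.name for c in all_categories}
        if unknown:
            raise ValueError(f"facilities with unknown categories: {sorted(unknown)}")
        kept, dropped = [], []
        for c in all_categories:
            (kept if c.name in present else dropped).append(c.name)
        if dropped:
            logger.warning("categories without facilities dropped: %s", dropped)
        self.categories = [c for c in all_categories if c.name in present]
        self.facilities = list(facilities)
        self.provider = provider or EuclideanProvider()
        self.di_metric = di_metric
        self.pressure_weighting = pressure_weighting
        self.pressure_normalization = pressure_normalization
        self.combine_on = combine_on
        self.zero_replacement = zero_replacement
        self.merge_tol = merge_tol

    @classmethod
    def from_frames(
        cls,
        units_df: pd.DataFrame,
        facilities_df: pd.DataFrame,
        **kwargs,
    ) -> "AccessibilityModel":
        """Build from DataFrames shaped like the CSV layer schemas."""
        def _opt(row, key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        units = []
        for rid, row in units_df.reset_index().iterrows():
            d = row.to_dict()
            units.append(
                ResidentialUnit(
                    id=str(d["id"]), x=float(d["x"]), y=float(d["y"]),
                    population=float(d["population"]),
                    iris_id=str(d["iris_id"]),
                    municipality_id=str(d["municipality_id"]),
                    epci_id=str(d["epci_id"]), region_id=str(d["region_id"]),
                    pop_women=_opt(d, "pop_women"), pop_0_19=_opt(d, "pop_0_19"),
                    pop_20_64=_opt(d, "pop_20_64"), pop_65p=_opt(d, "pop_65p"),
                ).validate()
            )
        facilities = []
        for rid, row in facilities_df.reset_index().iterrows():
            d = row.to_dict()
            facilities.append(
                Facility(
                    id=str(d["id"]), x=float(d["x"]), y=float(d["y"]),
                    category=str(d["category"]), capacity=int(d["capacity"]),
                    epci_id=_opt(d, "epci_id"), region_id=_opt(d, "region_id"),
                ).validate()
            )
        return cls(units, facilities, **kwargs)

    def fit(self) -> "AccessibilityResults":
        """Run the full pipeline and return the results object."""
        unit_ids = pd.Index([u.id for u in self.units], name="unit_id")
        pressures = pressure_tables(
            self.facilities,
            self.units,
            self.categories,
            pressure_normalization=self.pressure_normalization,
            merge_tol=self.merge_tol,
        )
        # catchments must see the same merged sites the pressure tables index
        merged = merge_colocated(self.facilities, tol=self.merge_tol)
        catchments: dict[str, CatchmentResult] = {}
        dap = pd.DataFrame(index=unit_ids)
        for cfg in self.categories:
            fac_c = [f for f in merged if f.category == cfg.name]
            res = category_surface(
                self.units,
                fac_c,
                pressures[cfg.name],
                provider=self.provider,
                category=cfg.name,
                di_metric=self.di_metric,
                pressure_weighting=self.pressure_weighting,
            )
            catchments[cfg.name] = res
            dap[cfg.name] = res.dap.values

        weights = {c.name: c.weight for c in self.categories}
        t_dap = pd.DataFrame(
            {
                c.name: idx.boxcox(dap[c.name].to_numpy(), c.lam,
                                   self.zero_replacement)
                for c in self.categories
            },
            index=unit_ids,
        )
        z = pd.DataFrame(
            {name: idx.standardize(t_dap[name].to_numpy()) for name in t_dap},
            index=unit_ids,
        )
        if self.combine_on == "z":
            combined = idx.combine(z, weights)
        else:
            combined = idx.combine(dap, weights)
        combined.index = unit_ids

        deciles = decile_bounds = None
        if len(combined) >= 10:
            dec, decile_bounds = idx.classify_deciles(combined.to_numpy())
            deciles = pd.Series(dec, index=unit_ids, name="decile")
        else:
            logger.warning(
                "%d units < 10: decile classification skipped", len(combined)
            )

        return AccessibilityResults(
            model=self,
            pressures=pressures,
            catchments=catchments,
            dap=dap,
            t_dap=t_dap,
            z=z,
            index=combined.rename("index"),
            deciles=deciles,
            decile_bounds=decile_bounds,
        )


class AccessibilityResults:
    """Fitted accessibility surface with all intermediate tables."""

    def __init__(self, model, pressures, catchments, dap, t_dap, z, index,
                 deciles, decile_bounds):
        self.model = model
        self.pressures: dict[str, pd.DataFrame] = pressures
        self.catchments: dict[str, CatchmentResult] = catchments
        self.dap: pd.DataFrame = dap
        self.t_dap: pd.DataFrame = t_dap
        self.z: pd.DataFrame = z
        self.index: pd.Series = index
        self.deciles: pd.Series | None = deciles
        self.decile_bounds: np.ndarray | None = decile_bounds

    # -- tables ------------------------------------------------------------

    @property
    def surface(self) -> pd.DataFrame:
        """Wide per-unit table: dap/t/z per category, index, decile."""
        parts = [
            self.dap.add_prefix("dap: "),
            self.t_dap.add_prefix("t: "),
            self.z.add_prefix("z: "),
            self.index.to_frame(),
        ]
        if self.deciles is not None:
            parts.append(self.deciles.to_frame())
        return pd.concat(parts, axis=1)

    def pressure_table(self) -> pd.DataFrame:
        """All categories' pressure tables stacked."""
        return pd.concat(self.pressures.values())

    def di_table(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "iris_id": iris, "di": v}
            for cat, res in self.catchments.items()
            for iris, v in res.di.items()
        ]
        return pd.DataFrame(rows)

    # -- scale changes and surfaces ----------------------------------------

    def aggregate(self, level: str, mode: str = "mean") -> pd.Series:
        """Index averaged to IRIS/municipality/EPCI/region."""
        if level not in _LEVEL_ATTR:
            raise ValueError(f"level must be one of {sorted(_LEVEL_ATTR)}")
        membership = pd.Series(
            {u.id: getattr(u, _LEVEL_ATTR[level]) for u in self.model.units}
        )
        populations = pd.Series({u.id: u.population for u in self.model.units})
        return idx.aggregate_scale(
            self.index, membership, mode=mode, populations=populations
        )

    def interpolate(
        self,
        query_xy: np.ndarray | None = None,
        k: int = 12,
        power: float = 2.0,
        resolution: float | None = None,
    ) -> pd.DataFrame:
        """IDW-interpolated index surface at ``query_xy`` (default: a
        regular grid over the units' bounding box)."""
        xy = np.array([[u.x, u.y] for u in self.model.units])
        if query_xy is None:
            bounds = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
            query_xy = idx.interpolation_grid(bounds, resolution)
        values = idx.idw_interpolate(xy, self.index.to_numpy(), query_xy,
                                     k=k, power=power)
        return pd.DataFrame(
            {"x": query_xy[:, 0], "y": query_xy[:, 1], "value": values}
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = []
        m = self.model
        lines.append("Spatial accessibility index (SCALe)")
        lines.append("=" * 60)
        lines.append(f"residential units: {len(m.units):>8d}")
        lines.append(f"facilities:        {len(m.facilities):>8d}")
        lines.append(f"categories:        {len(m.categories):>8d}")
        lines.append(f"distance provider: {m.provider!r}  (DI metric: {m.di_metric})")
        lines.append("")
        lines.append(f"{'category':<26} {'weight':>7} {'lam':>5} "
                     f"{'dap mean':>10} {'dap max':>10} {'pressure max':>12}")
        for c in m.categories:
            d = self.dap[c.name]
            p = self.pressures[c.name]["pressure"]
            lines.append(
                f"{c.name:<26} {c.weight:>7.3f} {c.lam:>5.2f} "
                f"{d.mean():>10.1f} {d.max():>10.1f} {p.max():>12.1f}"
            )
        lines.append("")
        q = self.index.quantile([0, 0.25, 0.5, 0.75, 1.0])
        lines.append(
            "index: min {:.3f} | q25 {:.3f} | median {:.3f} | q75 {:.3f} | "
            "max {:.3f}".format(*q.tolist())
        )
        lines.append("(low index = high accessibility; decile 10 = worst)")
        if self.decile_bounds is not None:
            b = ", ".join(f"{v:.2f}" for v in self.decile_bounds)
            lines.append(f"decile boundaries: [{b}]")
        return "\n".join(lines)

    def plot(self, ax=None, level: str | None = None):
        """Minimal debug scatter of the index surface (dark = inaccessible)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        xy = np.array([[u.x, u.y] for u in self.model.units])
        c = self.deciles if self.deciles is not None else self.index
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=np.asarray(c), cmap="Greys", s=12)
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        label = "decile (10 = worst)" if self.deciles is not None else "index"
        plt.colorbar(sc, ax=ax, label=label)
        return ax

    # -- persistence ---------------------------------------------------------

    def save(self, outdir) -> dict[str, str]:
        """Write all result tables as CSV/JSON; returns written paths."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}

        def _atomic_csv(df: pd.DataFrame, name: str, **kw):
            tmp = outdir / (name + ".tmp")
            df.to_csv(tmp, **kw)
            tmp.replace(outdir / name)
            written[name] = str(outdir / name)

        _atomic_csv(self.surface, "surface.csv")
        _atomic_csv(self.pressure_table(), "pressure.csv")
        _atomic_csv(self.di_table(), "di.csv", index=False)
        if self.decile_bounds is not None:
            tmp = outdir / "decile_bounds.json.tmp"
            with open(tmp, "w") as fh:
                json.dump({"bounds": list(self.decile_bounds)}, fh, indent=2)
            tmp.replace(outdir / "decile_bounds.json")
            written["decile_bounds.json"] = str(outdir / "decile_bounds.json")
        return written
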