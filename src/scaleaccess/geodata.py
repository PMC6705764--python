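"""Domain types and point-layer I/O for the accessibility pipeline.

Everything downstream works in planar metric coordinates (a projected CRS
such as Lambert-93 / EPSG:2154 for France): all distances are map-unit
distances, so layers arriving in geographic longitude/latitude are rejected
with an instruction to reproject first.

Two point layers drive the index:

* residential units — population-bearing points nested in the administrative
  hierarchy building -> IRIS -> municipality -> EPCI -> region;
* facilities — located health equipment with a category and a professional
  count (capacity).

A third input, the category configuration, carries the per-category
parameters of the index: the frequency weight ``W_e``, the Box-Cox exponent
``lambda``, the equipment range (primary vs tertiary) which fixes the
reference population scope (EPCI vs region), and the needy-population
selector (everyone, women only, under-19s only).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Fixed national shares used to impute needy subgroups when a layer does
#: not carry them (women ~51.5% of the population, under-19s ~24%).
DEFAULT_WOMEN_SHARE = 0.515
DEFAULT_AGE_0_19_SHARE = 0.24

HIERARCHY_LEVELS = ("iris_id", "municipality_id", "epci_id", "region_id")


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class CRSError(ValueError):
    """A layer is in geographic coordinates and must be reprojected."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidentialUnit:
    """A populated point (residential building) in the nested hierarchy."""

    id: str
    x: float
    y: float
    population: float
    iris_id: str
    municipality_id: str
    epci_id: str
    region_id: str
    pop_women: float | None = None
    pop_0_19: float | None = None
    pop_20_64: float | None = None
    pop_65p: float | None = None

    def validate(self) -> "ResidentialUnit":
        if not self.id:
            raise ValidationError("residential unit with empty id")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"unit {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.population) or self.population < 0:
            raise ValidationError(
                f"unit {self.id!r}: population must be a non-negative number, "
                f"got {self.population!r}"
            )
        for name in ("pop_women", "pop_0_19", "pop_20_64", "pop_65p"):
            v = getattr(self, name)
            if v is None:
                continue
            if v < 0 or v > self.population + 1e-9:
                raise ValidationError(
                    f"unit {self.id!r}: subgroup {name}={v} outside "
                    f"[0, population={self.population}]"
                )
        for level in HIERARCHY_LEVELS:
            if not getattr(self, level):
                raise ValidationError(f"unit {self.id!r}: empty {level}")
        return self

    def needy(self, selector: str) -> float:
        """Needy population under a selector, imputing fixed national shares
        when the subgroup is absent from the layer."""
        if selector == "all":
            return self.population
        if selector == "women":
            if self.pop_women is not None:
                return self.pop_women
            return self.population * DEFAULT_WOMEN_SHARE
        if selector == "age_0_19":
            if self.pop_0_19 is not None:
                return self.pop_0_19
            return self.population * DEFAULT_AGE_0_19_SHARE
        raise ValueError(f"unknown needy selector {selector!r}")


@dataclass(frozen=True)
class Facility:
    """A located equipment item: category plus professional count.

    Hierarchy membership is optional; when absent the pressure stage infers
    the facility's EPCI/region from the nearest residential unit.
    """

    id: str
    x: float
    y: float
    category: str
    capacity: int
    epci_id: str | None = None
    region_id: str | None = None

    def validate(self, known_categories: set[str] | None = None) -> "Facility":
        if not self.id:
            raise ValidationError("facility with empty id")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"facility {self.id!r}: non-finite coordinates")
        if int(self.capacity) != self.capacity or self.capacity < 1:
            raise ValidationError(
                f"facility {self.id!r}: capacity must be a positive integer, "
                f"got {self.capacity!r}"
            )
        if not self.category:
            raise ValidationError(f"facility {self.id!r}: empty category")
        if known_categories is not None and self.category not in known_categories:
            raise ValidationError(
                f"facility {self.id!r}: unknown category {self.category!r}"
            )
        return self


@dataclass(frozen=True)
class CategoryConfig:
    """Per-category parameters of the index.

    weight
        Frequency weight ``W_e`` — the national count of this equipment
        divided by the national count of general practitioners.
    lam
        Box-Cox exponent applied to the potential accessibility distance.
    range
        ``primary`` (frequent, local equipment) or ``tertiary`` (rare,
        specialised equipment); fixes the reference scope.
    reference_scope
        ``epci`` for primary equipment, ``region`` for tertiary.
    needy_selector
        Which population exerts pressure on the equipment: ``all``,
        ``women`` (gynaecology-obstetrics) or ``age_0_19`` (paediatrics).
    """

    name: str
    range: str
    weight: float
    lam: float
    reference_scope: str
    needy_selector: str = "all"

    def __post_init__(self) -> None:
        if self.range not in ("primary", "tertiary"):
            raise ValidationError(f"category {self.name!r}: range {self.range!r}")
        if self.reference_scope not in ("epci", "region"):
            raise ValidationError(
                f"category {self.name!r}: reference_scope {self.reference_scope!r}"
            )
        if self.range == "primary" and self.reference_scope != "epci":
            raise ValidationError(
                f"category {self.name!r}: primary range requires epci scope"
            )
        if self.range == "tertiary" and self.reference_scope != "region":
            raise ValidationError(
                f"category {self.name!r}: tertiary range requires region scope"
            )
        if self.needy_selector not in ("all", "women", "age_0_19"):
            raise ValidationError(
                f"category {self.name!r}: needy_selector {self.needy_selector!r}"
            )
        if not (self.weight > 0):
            raise ValidationError(f"category {self.name!r}: weight must be > 0")


# ---------------------------------------------------------------------------
# category set
# ---------------------------------------------------------------------------

# (name, range, weight, lambda, needy_selector) — weights are national
# equipment counts divided by the GP count (59,411), rounded half-up to 3
# decimals; lambdas were fixed per category by a normality fit.
_DEFAULT_CATEGORIES: tuple[tuple[str, str, float, float, str], ...] = (
    ("nurse", "primary", 1.225, 0.18, "all"),
    ("general practitioner", "primary", 1.0, 0.20, "all"),
    ("physiotherapist", "primary", 0.99, 0.20, "all"),
    ("dentist", "primary", 0.598, 0.22, "all"),
    ("pharmacist", "primary", 0.393, 0.21, "all"),
    ("gynaecology-obstetrics", "tertiary", 0.085, 0.12, "women"),
    ("ophthalmologist", "tertiary", 0.081, 0.13, "all"),
    ("paediatrician", "tertiary", 0.044, 0.12, "age_0_19"),
    ("short-stay care", "tertiary", 0.025, 0.10, "all"),
    ("accident and emergency", "tertiary", 0.010, 0.04, "all"),
)


def default_category_set() -> list[CategoryConfig]:
    """The ten health-equipment categories with their published parameters."""
    return [
        CategoryConfig(
            name=name,
            range=rng,
            weight=w,
            lam=lam,
            reference_scope="epci" if rng == "primary" else "region",
            needy_selector=selector,
        )
        for name, rng, w, lam, selector in _DEFAULT_CATEGORIES
    ]


def weight_from_counts(n_category: int, n_gp: int, decimals: int = 3) -> float:
    """Frequency weight of a category: its national equipment count divided
    by the national GP count, rounded half-up to ``decimals`` places."""
    if n_gp <= 0:
        raise ZeroDivisionError("GP count must be positive")
    ratio = Decimal(n_category) / Decimal(n_gp)
    q = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


def category_map(configs: Iterable[CategoryConfig]) -> dict[str, CategoryConfig]:
    out: dict[str, CategoryConfig] = {}
    for c in configs:
        if c.name in out:
            raise ValidationError(f"duplicate category {c.name!r}")
        out[c.name] = c
    return out


def read_category_config(path: str | Path) -> list[CategoryConfig]:
    """Read a category configuration from YAML or JSON.

    The file holds a list of mappings mirroring :class:`CategoryConfig`
    fields; ``reference_scope`` may be omitted (derived from ``range``).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError(f"{path}: category config must be a list")
    configs = []
    for entry in raw:
        entry = dict(entry)
        entry.setdefault(
            "reference_scope", "epci" if entry.get("range") == "primary" else "region"
        )
        entry.setdefault("needy_selector", "all")
        try:
            configs.append(CategoryConfig(**entry))
        except TypeError as exc:
            raise ValidationError(f"{path}: bad category entry {entry}: {exc}") from exc
    return configs


def write_category_config(configs: Sequence[CategoryConfig], path: str | Path) -> None:
    path = Path(path)
    payload = [
        {
            "name": c.name,
            "range": c.range,
            "weight": c.weight,
            "lam": c.lam,
            "reference_scope": c.reference_scope,
            "needy_selector": c.needy_selector,
        }
        for c in configs
    ]
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


def validate_hierarchy(units: Sequence[ResidentialUnit]) -> None:
    """Check that the administrative hierarchy is a tree: every identifier at
    one level maps to exactly one parent at the next."""
    for child, parent in zip(HIERARCHY_LEVELS[:-1], HIERARCHY_LEVELS[1:]):
        seen: dict[str, str] = {}
        for u in units:
            c, p = getattr(u, child), getattr(u, parent)
            if c in seen and seen[c] != p:
                raise ValidationError(
                    f"{child} {c!r} maps to two {parent} values: "
                    f"{seen[c]!r} and {p!r}"
                )
            seen[c] = p


def hierarchy_table(units: Sequence[ResidentialUnit]) -> pd.DataFrame:
    """One row per IRIS with its municipality, EPCI and region."""
    validate_hierarchy(units)
    rows = {
        u.iris_id: (u.iris_id, u.municipality_id, u.epci_id, u.region_id)
        for u in units
    }
    return pd.DataFrame(sorted(rows.values()), columns=list(HIERARCHY_LEVELS))


# ---------------------------------------------------------------------------
# point-layer I/O
# ---------------------------------------------------------------------------

_RESIDENTIAL_REQUIRED = ("id", "x", "y", "population") + HIERARCHY_LEVELS
_RESIDENTIAL_OPTIONAL = ("pop_women", "pop_0_19", "pop_20_64", "pop_65p")
_FACILITY_REQUIRED = ("id", "x", "y", "category", "capacity")
_FACILITY_OPTIONAL = ("epci_id", "region_id")


def _looks_geographic(records: list[dict]) -> bool:
    xs = [abs(float(r["x"])) for r in records if r.get("x") not in (None, "")]
    ys = [abs(float(r["y"])) for r in records if r.get("y") not in (None, "")]
    return bool(xs) and max(xs) <= 180.0 and max(ys) <= 90.0


def _records_from_geojson(path: Path) -> tuple[list[dict], bool]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    declared_planar = bool(gj.get("crs"))  # any declared CRS is taken as projected
    records = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: feature {i} is not a Point")
        props = dict(feat.get("properties") or {})
        props["x"], props["y"] = geom["coordinates"][:2]
        records.append(props)
    return records, declared_planar


def _records_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.to_dict("records")


def _get(rec: dict, key: str, path: Path, idx: int):
    if key not in rec or rec[key] in (None, ""):
        raise ValidationError(
            f"{path}: record {idx} (id={rec.get('id', '?')!r}) missing field {key!r}"
        )
    return rec[key]


def _opt_float(rec: dict, key: str) -> float | None:
    v = rec.get(key)
    if v in (None, ""):
        return None
    return float(v)


def read_points(path: str | Path, layer_kind: str,
                assume_planar: bool = False) -> list[ResidentialUnit] | list[Facility]:
    """Read a residential or facility point layer from GeoJSON or CSV.

    CSV layers are assumed to already be in a projected CRS.  GeoJSON layers
    without a declared CRS whose coordinates fit inside lon/lat bounds are
    rejected unless ``assume_planar`` is set: the pipeline computes metric
    distances and needs projected coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layer_kind not in ("residential", "facility"):
        raise ValueError(f"layer_kind must be residential|facility, got {layer_kind!r}")

    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        records, declared_planar = _records_from_geojson(path)
        if not declared_planar and not assume_planar and _looks_geographic(records):
            raise CRSError(
                f"{path}: coordinates look geographic (lon/lat); reproject the "
                "layer to a planar metric CRS (e.g. EPSG:2154) or declare a "
                "projected crs member / pass assume_planar=True"
            )
    elif suffix == ".csv":
        records = _records_from_csv(path)
    else:
        raise ValidationError(f"{path}: unsupported layer format {suffix!r}")

    out: list = []
    if layer_kind == "residential":
        for i, rec in enumerate(records):
            unit = ResidentialUnit(
                id=str(_get(rec, "id", path, i)),
                x=float(_get(rec, "x", path, i)),
                y=float(_get(rec, "y", path, i)),
                population=float(_get(rec, "population", path, i)),
                iris_id=str(_get(rec, "iris_id", path, i)),
                municipality_id=str(_get(rec, "municipality_id", path, i)),
                epci_id=str(_get(rec, "epci_id", path, i)),
                region_id=str(_get(rec, "region_id", path, i)),
                pop_women=_opt_float(rec, "pop_women"),
                pop_0_19=_opt_float(rec, "pop_0_19"),
                pop_20_64=_opt_float(rec, "pop_20_64"),
                pop_65p=_opt_float(rec, "pop_65p"),
            )
            out.append(unit.validate())
        validate_hierarchy(out)
    else:
        for i, rec in enumerate(records):
            fac = Facility(
                id=str(_get(rec, "id", path, i)),
                x=float(_get(rec, "x", path, i)),
                y=float(_get(rec, "y", path, i)),
                category=str(_get(rec, "category", path, i)),
                capacity=int(float(_get(rec, "capacity", path, i))),
                epci_id=str(rec["epci_id"]) if rec.get("epci_id") else None,
                region_id=str(rec["region_id"]) if rec.get("region_id") else None,
            )
            out.append(fac.validate())
    logger.info("read %d %s records from %s", len(out), layer_kind, path)
    return out


def _record_fields(obj) -> dict:
    d = {}
    for f in dc_fields(obj):
        v = getattr(obj, f.name)
        if v is not None:
            d[f.name] = v
    return d


def write_points(records: Sequence[ResidentialUnit] | Sequence[Facility],
                 path: str | Path) -> None:
    """Write a point layer as CSV or GeoJSON (format chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        if isinstance(records[0], ResidentialUnit):
            cols = list(_RESIDENTIAL_REQUIRED) + [
                c for c in _RESIDENTIAL_OPTIONAL
                if any(getattr(r, c) is not None for r in records)
            ]
        else:
            cols = list(_FACILITY_REQUIRED) + [
                c for c in _FACILITY_OPTIONAL
                if any(getattr(r, c) is not None for r in records)
            ]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            w.writeheader()
            for r in records:
                row = {c: getattr(r, c) for c in cols if getattr(r, c) is not None}
                w.writerow(row)
    elif suffix in (".geojson", ".json"):
        features = []
        for r in records:
            props = _record_fields(r)
            x, y = props.pop("x"), props.pop("y")
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": props,
                }
            )
        gj = {
            "type": "FeatureCollection",
            # planar metric coordinates; declared so readers do not mistake
            # them for lon/lat
            "crs": {"type": "name", "properties": {"name": "urn:x-scaleaccess:planar-metres"}},
            "features": features,
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)
    else:
        raise ValidationError(f"{path}: unsupported output format {suffix!r}")
    logger.info("wrote %d records to %s", len(records), path)


def units_frame(units: Sequence[ResidentialUnit]) -> pd.DataFrame:
    """Residential units as a DataFrame indexed by unit id."""
    df = pd.DataFrame([_record_fields(u) for u in units])
    return df.set_index("id")


def facilities_frame(facilities: Sequence[Facility]) -> pd.DataFrame:
    """Facilities as a DataFrame indexed by facility id."""
    df = pd.DataFrame([_record_fields(f) for f in facilities])
    return df.set_index("id")
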