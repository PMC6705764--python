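"""Seeded synthetic territories with a French-style nested hierarchy.

The generator emulates the end product of projecting census population onto
residential buildings: populated points nested in building -> IRIS ->
municipality -> EPCI -> region, with facility patterns clustered in urban
IRIS.  It exists so every pipeline stage is testable without any registry
download; it makes no claim to realistic French geography.

Layout: regions are vertical strips of the extent, EPCI horizontal strips
within a region, IRIS Gaussian point clusters around centres drawn inside
the EPCI rectangle.  Unit populations follow a lognormal law whose mean
matches the national residential-building average (~23 inhabitants, heavily
right-skewed); urban units are inflated to mimic collective housing.
Facility counts per category and region are Poisson with mean
``density × needy population / 10,000`` (never below one per region, so
every tertiary catchment is computable), placed preferentially in urban,
populous IRIS.

Random draws come from per-purpose streams sub-seeded from the territory
seed, so adding a category never perturbs unit generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geodata import (
    CategoryConfig,
    Facility,
    ResidentialUnit,
    default_category_set,
    hierarchy_table,
)

#: Expected facilities per 10,000 needy residents, from national equipment
#: counts over ~62.7M inhabitants (women / under-19 bases for the needy
#: categories).
DEFAULT_FACILITY_DENSITY: dict[str, float] = {
    "nurse": 11.6,
    "general practitioner": 9.5,
    "physiotherapist": 9.4,
    "dentist": 5.7,
    "pharmacist": 3.7,
    "gynaecology-obstetrics": 1.6,
    "ophthalmologist": 0.77,
    "paediatrician": 1.7,
    "short-stay care": 0.24,
    "accident and emergency": 0.10,
}

#: Lognormal population law: mean exp(mu + sigma^2/2) ~ 22.8 inhabitants
#: per residential unit, median ~7 — strongly right-skewed like real
#: building populations.
DEFAULT_POPULATION_LAW = ("lognormal", 2.0, 1.5)


class Territory(NamedTuple):
    units: list[ResidentialUnit]
    facilities: list[Facility]
    hierarchy: pd.DataFrame
    #: per-IRIS metadata: centre coordinates and urban flag
    iris_info: pd.DataFrame = pd.DataFrame()


@dataclass
class TerritorySpec:
    """Parameters of a synthetic territory.

    Counts multiply: ``n_regions × n_epci_per_region × n_iris_per_epci ×
    n_units_per_iris`` residential units in total.  ``facility_density``
    maps category name to expected facilities per 10,000 needy residents.
    ``extent`` is ``(xmin, ymin, xmax, ymax)`` in metres.
    """

    seed: int = 0
    n_regions: int = 2
    n_epci_per_region: int = 2
    n_municipalities_per_epci: int = 2
    n_iris_per_epci: int = 4
    n_units_per_iris: int = 12
    urban_fraction: float = 0.3
    facility_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACILITY_DENSITY)
    )
    extent: tuple[float, float, float, float] = (0.0, 0.0, 200_000.0, 200_000.0)
    population_law: tuple = DEFAULT_POPULATION_LAW
    urban_pop_factor: float = 4.0     # collective housing in urban IRIS
    urban_weight: float = 8.0         # facility-placement preference
    capacity_mean: dict[str, float] = field(
        default_factory=lambda: {"primary": 2.0, "tertiary": 5.0}
    )

    def validate(self, categories: Sequence[CategoryConfig]) -> None:
        for name in ("n_regions", "n_epci_per_region", "n_municipalities_per_epci",
                     "n_iris_per_epci", "n_units_per_iris"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must lie in [0, 1]")
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate extent")
        for cfg in categories:
            d = self.facility_density.get(cfg.name)
            if d is None or d <= 0:
                raise ValueError(
                    f"category {cfg.name!r}: facility_density must be > 0 "
                    "(raise the density so at least one facility can exist)"
                )


def _population(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind = law[0]
    if kind == "lognormal":
        _, mu, sigma = law
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    raise ValueError(f"unknown population law {kind!r}")


def generate_territory(
    spec: TerritorySpec,
    categories: Sequence[CategoryConfig] | None = None,
) -> Territory:
    """Generate a deterministic synthetic territory for a category set."""
    categories = list(categories) if categories is not None else default_category_set()
    spec.validate(categories)

    xmin, ymin, xmax, ymax = spec.extent
    region_w = (xmax - xmin) / spec.n_regions
    epci_h = (ymax - ymin) / spec.n_epci_per_region

    rng_units = np.random.default_rng([int(spec.seed), 1])

    units: list[ResidentialUnit] = []
    iris_centres: dict[str, tuple[float, float]] = {}
    iris_urban: dict[str, bool] = {}
    uid = 0
    n_urban = int(round(spec.urban_fraction * spec.n_iris_per_epci))
    cluster_sd_urban = min(region_w, epci_h) / 20.0
    cluster_sd_rural = min(region_w, epci_h) / 8.0

    for r in range(spec.n_regions):
        region_id = f"R{r + 1:02d}"
        rx0 = xmin + r * region_w
        for e in range(spec.n_epci_per_region):
            epci_id = f"{region_id}-E{e + 1:02d}"
            ey0 = ymin + e * epci_h
            urban_flags = np.zeros(spec.n_iris_per_epci, dtype=bool)
            urban_flags[
                rng_units.choice(spec.n_iris_per_epci, size=n_urban, replace=False)
            ] = True
            for i in range(spec.n_iris_per_epci):
                iris_id = f"{epci_id}-I{i + 1:03d}"
                mun = i % spec.n_municipalities_per_epci
                mun_id = f"{epci_id}-M{mun + 1:02d}"
                cx = rng_units.uniform(rx0 + 0.05 * region_w, rx0 + 0.95 * region_w)
                cy = rng_units.uniform(ey0 + 0.05 * epci_h, ey0 + 0.95 * epci_h)
                iris_centres[iris_id] = (cx, cy)
                iris_urban[iris_id] = bool(urban_flags[i])
                sd = cluster_sd_urban if urban_flags[i] else cluster_sd_rural
                xy = rng_units.normal(
                    loc=(cx, cy), scale=sd, size=(spec.n_units_per_iris, 2)
                )
                pop = _population(rng_units, spec.population_law, spec.n_units_per_iris)
                if urban_flags[i]:
                    pop = pop * spec.urban_pop_factor
                s_women = np.clip(rng_units.normal(0.515, 0.02, spec.n_units_per_iris), 0.3, 0.7)
                s_0_19 = np.clip(rng_units.normal(0.24, 0.03, spec.n_units_per_iris), 0.05, 0.5)
                s_65p = np.clip(rng_units.normal(0.20, 0.03, spec.n_units_per_iris), 0.02, 0.5)
                for j in range(spec.n_units_per_iris):
                    uid += 1
                    p = float(pop[j])
                    units.append(
                        ResidentialUnit(
                            id=f"u{uid:06d}",
                            x=float(xy[j, 0]),
                            y=float(xy[j, 1]),
                            population=p,
                            pop_women=p * float(s_women[j]),
                            pop_0_19=p * float(s_0_19[j]),
                            pop_20_64=p * float(1.0 - s_0_19[j] - s_65p[j]),
                            pop_65p=p * float(s_65p[j]),
                            iris_id=iris_id,
                            municipality_id=mun_id,
                            epci_id=epci_id,
                            region_id=region_id,
                        )
                    )

    iris_ids = sorted(iris_centres)
    iris_region = {i: i.split("-")[0] for i in iris_ids}
    iris_pop = {i: 0.0 for i in iris_ids}
    for u in units:
        iris_pop[u.iris_id] += u.population

    facilities: list[Facility] = []
    iris_epci = {i: i.rsplit("-I", 1)[0] for i in iris_ids}
    for k, cfg in enumerate(categories):
        rng_c = np.random.default_rng([int(spec.seed), 2, k])
        density = spec.facility_density[cfg.name]
        cap_mean = spec.capacity_mean[cfg.range]
        fid = 0
        slug = cfg.name.replace(" ", "-")
        # facilities are drawn per reference scope (EPCI for primary
        # equipment, region for tertiary), never fewer than one per scope so
        # every catchment and pressure table is computable
        scope_of = iris_epci if cfg.reference_scope == "epci" else iris_region
        unit_scope_attr = f"{cfg.reference_scope}_id"
        for scope in sorted(set(scope_of.values())):
            needy = sum(
                u.needy(cfg.needy_selector)
                for u in units
                if getattr(u, unit_scope_attr) == scope
            )
            n_fac = max(1, int(rng_c.poisson(density * needy / 10_000.0)))
            region_iris = [i for i in iris_ids if scope_of[i] == scope]
            w = np.array(
                [
                    iris_pop[i] * (spec.urban_weight if iris_urban[i] else 1.0)
                    for i in region_iris
                ]
            )
            w = w / w.sum()
            chosen = rng_c.choice(len(region_iris), size=n_fac, p=w)
            for c in chosen:
                iris_id = region_iris[int(c)]
                cx, cy = iris_centres[iris_id]
                x, y = rng_c.normal(
                    loc=(cx, cy), scale=cluster_sd_urban / 2.0, size=2
                )
                fid += 1
                facilities.append(
                    Facility(
                        id=f"f-{slug}-{scope}-{fid:04d}",
                        x=float(x),
                        y=float(y),
                        category=cfg.name,
                        capacity=1 + int(rng_c.poisson(cap_mean - 1.0)),
                        epci_id=iris_epci[iris_id],
                        region_id=iris_region[iris_id],
                    )
                )

    iris_info = pd.DataFrame(
        {
            "iris_id": iris_ids,
            "centre_x": [iris_centres[i][0] for i in iris_ids],
            "centre_y": [iris_centres[i][1] for i in iris_ids],
            "urban": [iris_urban[i] for i in iris_ids],
        }
    )
    return Territory(units=units, facilities=facilities,
                     hierarchy=hierarchy_table(units), iris_info=iris_info)


# ---------------------------------------------------------------------------
# worked example — hand-checkable regression fixture
# ---------------------------------------------------------------------------


class WorkedExample(NamedTuple):
    units: list[ResidentialUnit]
    facilities: list[Facility]
    categories: list[CategoryConfig]
    expected: dict


def make_worked_example() -> WorkedExample:
    """A 2-IRIS, 6-unit, 4-facility, 2-category instance with every
    intermediate quantity worked out by hand.

    Geometry (planar metres): GP offices g1=(0,0) cap 2 and g2=(1,-3) cap 4;
    nurse offices n1=(0,0) cap 1 and n2=(1,-3) cap 4.  IRIS A holds units
    u1..u3 north of the facilities, IRIS B units u4..u6 around g2/n2.  The
    3-4-5 triangle between u2=(3,4) and g1=(0,0) makes DI(A)=5; u1 sits at
    distances {1,3} from the two GP sites whose pressures are {3,1}, giving
    DAP(u1) = (3·1+1·3)/4 = 1.5.
    """
    H = dict(municipality_id="MUN-1", epci_id="EPCI-1", region_id="REG-1")
    units = [
        ResidentialUnit(id="u1", x=1, y=0, population=2, iris_id="IRIS-A", **H),
        ResidentialUnit(id="u2", x=3, y=4, population=2, iris_id="IRIS-A", **H),
        ResidentialUnit(id="u3", x=0, y=2, population=2, iris_id="IRIS-A", **H),
        ResidentialUnit(id="u4", x=1, y=-4, population=2, iris_id="IRIS-B", **H),
        ResidentialUnit(id="u5", x=2, y=-3, population=1, iris_id="IRIS-B", **H),
        ResidentialUnit(id="u6", x=0, y=-3, population=1, iris_id="IRIS-B", **H),
    ]
    facilities = [
        Facility(id="g1", x=0, y=0, category="general practitioner", capacity=2),
        Facility(id="g2", x=1, y=-3, category="general practitioner", capacity=4),
        Facility(id="n1", x=0, y=0, category="nurse", capacity=1),
        Facility(id="n2", x=1, y=-3, category="nurse", capacity=4),
    ]
    categories = [
        CategoryConfig(name="general practitioner", range="primary", weight=1.0,
                       lam=0.20, reference_scope="epci"),
        CategoryConfig(name="nurse", range="primary", weight=1.225,
                       lam=0.18, reference_scope="epci"),
    ]
    # Voronoi halves: {u1,u2,u3} -> site (0,0), {u4,u5,u6} -> site (1,-3),
    # so assigned populations are 6 and 4 for both categories.
    expected = {
        "assigned": {
            "general practitioner": {"g1": 6.0, "g2": 4.0},
            "nurse": {"n1": 6.0, "n2": 4.0},
        },
        "pressure": {
            "general practitioner": {"g1": 3.0, "g2": 1.0},
            "nurse": {"n1": 6.0, "n2": 1.0},
        },
        "di": {
            "general practitioner": {"IRIS-A": 5.0, "IRIS-B": 1.0},
            "nurse": {"IRIS-A": 5.0, "IRIS-B": 1.0},
        },
        "zap": {
            "general practitioner": {
                "u1": ("g1", "g2"), "u2": ("g1",), "u3": ("g1",),
                "u4": ("g2",), "u5": ("g2",), "u6": ("g2",),
            },
            "nurse": {
                "u1": ("n1", "n2"), "u2": ("n1",), "u3": ("n1",),
                "u4": ("n2",), "u5": ("n2",), "u6": ("n2",),
            },
        },
        "dap": {
            "general practitioner":
                {"u1": 1.5, "u2": 5.0, "u3": 2.0, "u4": 1.0, "u5": 1.0, "u6": 1.0},
            "nurse":
                {"u1": 9.0 / 7.0, "u2": 5.0, "u3": 2.0,
                 "u4": 1.0, "u5": 1.0, "u6": 1.0},
        },
        # Box-Cox with lam 0.20 (GP) / 0.18 (nurse), then z with sample sd;
        # frozen from an independent straight-line recomputation.
        "t_dap": {
            "general practitioner": {
                "u1": 0.42235885598849277, "u2": 1.8986483073060745,
                "u3": 0.7434917749851755, "u4": 0.0, "u5": 0.0, "u6": 0.0,
            },
            "nurse": {
                "u1": 0.2570854240927672, "u2": 1.866805828133696,
                "u3": 0.7382438071988807, "u4": 0.0, "u5": 0.0, "u6": 0.0,
            },
        },
        "z": {
            "general practitioner": {
                "u1": -0.11873729567992729, "u2": 1.8643908782088379,
                "u3": 0.31264676566188915, "u4": -0.6861001160635999,
                "u5": -0.6861001160635999, "u6": -0.6861001160635999,
            },
            "nurse": {
                "u1": -0.2976061231300322, "u2": 1.8805742733339408,
                "u3": 0.3534695264331393, "u4": -0.6454792255456827,
                "u5": -0.6454792255456827, "u6": -0.6454792255456827,
            },
        },
        # index = 1.0 * z_gp + 1.225 * z_nurse
        "index": {
            "u1": -0.48330479651421676, "u2": 4.168094363042916,
            "u3": 0.7456469355424848, "u4": -1.4768121673570613,
            "u5": -1.4768121673570613, "u6": -1.4768121673570613,
        },
    }
    return WorkedExample(units=units, facilities=facilities,
                         categories=categories, expected=expected)
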