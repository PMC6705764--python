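from __future__ import annotations

import numpy as np
import pytest

from scaleaccess import (
    CategoryConfig,
    Facility,
    ResidentialUnit,
    TerritorySpec,
    generate_territory,
    make_worked_example,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def small_territory():
    """A modest seeded territory used by several end-to-end tests."""
    return generate_territory(TerritorySpec(seed=123))


def random_instance(seed: int, n_units: int | None = None, n_fac: int | None = None,
                    n_iris: int = 3):
    """A random single-category instance (<=100 units, <=20 facilities)."""
    rng = np.random.default_rng(seed)
    n_units = n_units or int(rng.integers(10, 101))
    n_fac = n_fac or int(rng.integers(2, 21))
    units = []
    for i in range(n_units):
        units.append(
            ResidentialUnit(
                id=f"u{i:03d}",
                x=float(rng.uniform(0, 1000)),
                y=float(rng.uniform(0, 1000)),
                population=float(rng.uniform(1, 50)),
                iris_id=f"I{i % n_iris}",
                municipality_id="M0",
                epci_id="E0",
                region_id="R0",
            )
        )
    facilities = [
        Facility(
            id=f"f{j:03d}",
            x=float(rng.uniform(0, 1000)),
            y=float(rng.uniform(0, 1000)),
            category="general practitioner",
            capacity=int(rng.integers(1, 6)),
            epci_id="E0",
            region_id="R0",
        )
        for j in range(n_fac)
    ]
    config = CategoryConfig(
        name="general practitioner", range="primary", weight=1.0,
        lam=0.20, reference_scope="epci",
    )
    return units, facilities, config
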