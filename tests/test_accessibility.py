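import numpy as np
import pytest

import _oracles as oracle
from scaleaccess import (
    EuclideanProvider,
    Facility,
    MatrixProvider,
    MinkowskiProvider,
    ResidentialUnit,
    assign_population,
    category_surface,
    compute_dap,
    compute_di,
    select_zap,
)
from scaleaccess.distances import DistanceLookupError, parse_provider
from conftest import random_instance

UNIT_KW = dict(iris_id="I1", municipality_id="M1", epci_id="E1", region_id="R1")


def unit(id, x, y, pop=1.0, iris="I1"):
    kw = dict(UNIT_KW, iris_id=iris)
    return ResidentialUnit(id=id, x=x, y=y, population=pop, **kw)


def gp(id, x, y, cap=1):
    return Facility(id=id, x=x, y=y, category="general practitioner",
                    capacity=cap, epci_id="E1", region_id="R1")


class TestDistanceProviders:
    def test_euclidean_345(self):
        assert EuclideanProvider().distance((0, 0), (3, 4)) == 5.0

    def test_minkowski_125(self):
        d = MinkowskiProvider(p=1.25).distance((0, 0), (1, 1))
        assert d == pytest.approx(2 ** 0.8, rel=1e-12)  # (1+1)^(1/1.25)

    def test_minkowski_p2_is_euclidean(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 10, size=(2, 5, 2))
        assert np.allclose(
            MinkowskiProvider(p=2).pairwise(a, b),
            EuclideanProvider().pairwise(a, b),
        )

    def test_matrix_lookup_and_missing_pair(self):
        prov = MatrixProvider({("u1", "f1"): 7.5})
        assert prov.distance((0, 0), (9, 9), "u1", "f1") == 7.5
        with pytest.raises(DistanceLookupError, match="u1.*f2"):
            prov.distance((0, 0), (9, 9), "u1", "f2")

    def test_parse_provider_specs(self):
        assert parse_provider("euclidean").kind == "euclidean"
        assert parse_provider("minkowski:1.25").p == 1.25
        with pytest.raises(ValueError):
            parse_provider("warp-drive")

    def test_minkowski_exponent_below_one_rejected(self):
        with pytest.raises(ValueError):
            MinkowskiProvider(p=0.5)


class TestComputeDi:
    def test_coincident_unit_gives_zero(self):
        assert compute_di([unit("u", 0, 0)], [gp("f", 0, 0)]) == 0.0

    def test_closed_form_345(self):
        units = [unit("a", 0, 0), unit("b", 3, 4)]
        assert compute_di(units, [gp("f", 0, 0)]) == 5.0

    def test_no_facilities_is_an_error(self):
        with pytest.raises(ValueError, match="facilit"):
            compute_di([unit("u", 0, 0)], [])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_max_of_min_oracle(self, seed):
        rng = np.random.default_rng(seed)
        units = [unit(f"u{i}", *rng.uniform(0, 100, 2)) for i in range(5)]
        facs = [gp(f"f{j}", *rng.uniform(0, 100, 2)) for j in range(3)]
        expected = oracle.di(
            {u.id: (u.x, u.y) for u in units}, {f.id: (f.x, f.y) for f in facs}
        )
        assert compute_di(units, facs) == pytest.approx(expected, rel=1e-12)


class TestSelectZap:
    def test_boundary_inclusive(self):
        u = unit("u", 0, 0)
        facs = [gp("a", 3, 4), gp("b", 5, 0), gp("c", 4, 4), gp("d", 6, 0)]
        assert set(select_zap(u, 5.0, facs)) == {"a", "b"}

    def test_zero_radius_keeps_coincident_facility(self):
        u = unit("u", 2, 2)
        assert select_zap(u, 0.0, [gp("f", 2, 2), gp("g", 3, 3)]) == ("f",)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        u = unit("u", *rng.uniform(0, 100, 2))
        facs = [gp(f"f{j}", *rng.uniform(0, 100, 2)) for j in range(12)]
        radius = float(rng.uniform(10, 80))
        expected = oracle.zap(
            (u.x, u.y), radius, {f.id: (f.x, f.y) for f in facs}
        )
        assert set(select_zap(u, radius, facs)) == expected


class TestComputeDap:
    def test_single_facility_any_pressure(self):
        u = unit("u", 0, 0)
        facs = [gp("f", 4, 0)]
        assert compute_dap(u, ["f"], {"f": 17.0}, facs) == 4.0

    def test_equal_pressures_give_plain_mean(self):
        u = unit("u", 0, 0)
        facs = [gp("a", 2, 0), gp("b", 4, 0)]
        assert compute_dap(u, ["a", "b"], {"a": 1.0, "b": 1.0}, facs) == 3.0

    def test_pressure_weighted_closed_form(self):
        u = unit("u", 0, 0)
        facs = [gp("a", 1, 0), gp("b", 3, 0)]
        assert compute_dap(u, ["a", "b"], {"a": 3.0, "b": 1.0}, facs) == 1.5

    def test_zero_pressure_falls_back_to_unweighted_mean(self):
        u = unit("u", 0, 0)
        facs = [gp("a", 1, 0), gp("b", 3, 0)]
        assert compute_dap(u, ["a", "b"], {"a": 0.0, "b": 0.0}, facs) == 2.0

    def test_empty_zap_is_a_contract_violation(self):
        with pytest.raises(ValueError, match="empty ZAP"):
            compute_dap(unit("u", 0, 0), [], {}, [])

    def test_inverse_pressure_reading(self):
        u = unit("u", 0, 0)
        facs = [gp("a", 1, 0), gp("b", 3, 0)]
        d = compute_dap(u, ["a", "b"], {"a": 3.0, "b": 1.0}, facs,
                        pressure_weighting="inverse_pressure")
        assert d == pytest.approx((1 / 3 * 1 + 1 * 3) / (1 / 3 + 1))


def _surface(units, facilities, config, provider=None):
    pressures = assign_population(
        facilities, units, needy_selector=config.needy_selector,
        reference_scope=config.reference_scope,
    )
    return category_surface(units, facilities, pressures, provider=provider,
                            category=config.name)


class TestCategorySurface:
    def test_single_unit_single_facility(self):
        units = [unit("u", 0, 0, pop=5)]
        facs = [gp("f", 3, 4, cap=2)]
        _, _, config = random_instance(0)
        res = _surface(units, facs, config)
        assert res.dap["u"] == 5.0
        assert res.di == {"I1": 5.0}

    def test_all_units_coincident_with_facilities(self):
        units = [unit(f"u{i}", i, 0, pop=2) for i in range(3)]
        facs = [gp(f"f{i}", i, 0) for i in range(3)]
        _, _, config = random_instance(0)
        res = _surface(units, facs, config)
        assert (res.dap == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_pipeline_matches_straight_line_oracle(self, seed):
        units, facs, config = random_instance(seed, n_units=30, n_fac=6)
        res = _surface(units, facs, config)
        units_xy = {u.id: (u.x, u.y) for u in units}
        fac_xy = {f.id: (f.x, f.y) for f in facs}
        pressures = oracle.pressure(
            units_xy, {u.id: u.population for u in units},
            fac_xy, {f.id: f.capacity for f in facs},
        )
        for iris in {u.iris_id for u in units}:
            iris_units = {u.id: units_xy[u.id] for u in units if u.iris_id == iris}
            di = oracle.di(iris_units, fac_xy)
            assert res.di[iris] == pytest.approx(di, rel=1e-12)
            for uid in iris_units:
                z = oracle.zap(units_xy[uid], di, fac_xy)
                assert set(res.zap[uid]) == z
                expected = oracle.dap(units_xy[uid], sorted(z), fac_xy, pressures)
                assert res.dap[uid] == pytest.approx(expected, rel=1e-9)

    def test_dap_bounded_by_zap_distances(self):
        units, facs, config = random_instance(3, n_units=40, n_fac=8)
        res = _surface(units, facs, config)
        fac_xy = {f.id: (f.x, f.y) for f in facs}
        for u in units:
            ds = [oracle.dist((u.x, u.y), fac_xy[f]) for f in res.zap[u.id]]
            assert min(ds) - 1e-9 <= res.dap[u.id] <= max(ds) + 1e-9

    def test_scale_equivariance(self):
        units, facs, config = random_instance(4, n_units=25, n_fac=5)
        res1 = _surface(units, facs, config)
        s = 3.7
        units_s = [
            ResidentialUnit(id=u.id, x=u.x * s, y=u.y * s,
                            population=u.population, iris_id=u.iris_id,
                            municipality_id=u.municipality_id,
                            epci_id=u.epci_id, region_id=u.region_id)
            for u in units
        ]
        facs_s = [
            Facility(id=f.id, x=f.x * s, y=f.y * s, category=f.category,
                     capacity=f.capacity, epci_id=f.epci_id,
                     region_id=f.region_id)
            for f in facs
        ]
        res2 = _surface(units_s, facs_s, config)
        assert np.allclose(res2.dap, res1.dap * s)
        for iris in res1.di:
            assert res2.di[iris] == pytest.approx(res1.di[iris] * s)

    @pytest.mark.parametrize("factor", [1.5, 5.0])
    def test_moving_facilities_radially_away_never_decreases_dap(self, factor):
        # every facility pushed radially away from the fixed unit, with the
        # catchment and pressures held fixed
        units, facs, config = random_instance(5, n_units=12, n_fac=6)
        u = units[0]
        pressures = {f.id: float(i % 3) for i, f in enumerate(facs)}
        zap = [f.id for f in facs]
        d1 = compute_dap(u, zap, pressures, facs)
        far = [
            Facility(id=f.id, x=u.x + factor * (f.x - u.x),
                     y=u.y + factor * (f.y - u.y), category=f.category,
                     capacity=f.capacity, epci_id=f.epci_id,
                     region_id=f.region_id)
            for f in facs
        ]
        d2 = compute_dap(u, zap, pressures, far)
        assert d2 >= d1

    def test_matrix_provider_reproduces_euclidean(self):
        units, facs, config = random_instance(6, n_units=20, n_fac=5)
        entries = {
            (u.id, f.id): oracle.dist((u.x, u.y), (f.x, f.y))
            for u in units
            for f in facs
        }
        res_e = _surface(units, facs, config)
        res_m = _surface(units, facs, config, provider=MatrixProvider(entries))
        assert np.allclose(res_e.dap, res_m.dap)
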