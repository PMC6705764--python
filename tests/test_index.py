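import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from scaleaccess import (
    aggregate_scale,
    boxcox,
    classify_deciles,
    combine,
    idw_interpolate,
    standardize,
)
from scaleaccess.index import interpolation_grid


class TestBoxcox:
    @pytest.mark.parametrize("lam", [0.0, 0.04, 0.18, 0.22, 1.0])
    def test_unit_distance_maps_to_zero(self, lam):
        assert boxcox(1.0, lam) == 0.0

    def test_closed_form_32_lam_02(self):
        # 32^0.2 = 2, so (2 - 1) / 0.2 = 5
        assert boxcox(32.0, 0.20) == pytest.approx(5.0, rel=1e-12)

    def test_zero_distance_replacement(self):
        expected = (10 ** -1.4 - 1) / 0.2  # ((1e-7)^0.2 - 1)/0.2
        assert boxcox(0.0, 0.20) == pytest.approx(expected, rel=1e-12)
        assert boxcox(0.0, 0.20) == pytest.approx(-4.80095, abs=5e-6)

    def test_lambda_zero_is_log_and_is_the_limit(self):
        x = np.array([0.5, 2.0, 100.0])
        assert np.allclose(boxcox(x, 0.0), np.log(x))
        assert np.allclose(boxcox(x, 1e-8), np.log(x), atol=1e-6)

    def test_matches_scipy_special(self):
        from scipy.special import boxcox as scipy_boxcox

        x = np.linspace(0.1, 500, 40)
        for lam in (0.04, 0.12, 0.20):
            assert np.allclose(boxcox(x, lam), scipy_boxcox(x, lam))

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
        st.sampled_from([0.0, 0.04, 0.10, 0.20, 0.5]),
    )
    @settings(deadline=None, derandomize=True)
    def test_strictly_increasing(self, a, b, lam):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert boxcox(lo, lam) < boxcox(hi, lam)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            boxcox(-1.0, 0.2)


class TestStandardize:
    def test_simple_triplet(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.lognormal(size=200))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_matches_two_pass_reference(self):
        v = [2, 4, 4, 4, 5, 5, 7, 9]
        assert np.allclose(standardize(v), oracle.standardize(v), rtol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        v = rng.normal(10, 3, 50)
        z = standardize(v)
        assert np.allclose(standardize(z), z, atol=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([4.0, 4.0, 4.0])


class TestCombine:
    def test_all_zero_gives_zero(self):
        z = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0]})
        assert (combine(z, {"a": 1.0, "b": 0.5}) == 0).all()

    def test_two_category_closed_form(self):
        z = pd.DataFrame({"a": [2.0], "b": [-2.0]})
        assert combine(z, {"a": 1.0, "b": 0.5}).iloc[0] == 1.0

    def test_ten_categories_match_dot_product(self):
        from scaleaccess import default_category_set

        rng = np.random.default_rng(2)
        cats = default_category_set()
        weights = {c.name: c.weight for c in cats}
        z = pd.DataFrame(
            rng.normal(size=(30, 10)), columns=list(weights),
            index=[f"u{i}" for i in range(30)],
        )
        got = combine(z, weights)
        expected = oracle.combine(
            {c: z[c].to_dict() for c in z}, weights, z.index
        )
        assert np.allclose(got, expected, rtol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        w = {"a": 1.0, "b": 0.3}
        z1 = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        z2 = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        lhs = combine(2.0 * z1 + 3.0 * z2, w)
        rhs = 2.0 * combine(z1, w) + 3.0 * combine(z2, w)
        assert np.allclose(lhs, rhs)

    def test_missing_category_named_in_error(self):
        z = pd.DataFrame({"a": [1.0]})
        with pytest.raises(KeyError, match="b"):
            combine(z, {"a": 1.0, "b": 1.0})


class TestDeciles:
    def test_one_value_per_bin(self):
        deciles, _ = classify_deciles(np.arange(1.0, 11.0))
        assert list(deciles) == list(range(1, 11))

    def test_maximum_lands_in_decile_10(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        deciles, _ = classify_deciles(v)
        assert deciles[np.argmax(v)] == 10
        assert deciles[np.argmin(v)] == 1

    def test_uniform_values_fill_bins_evenly(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(size=1000)
        deciles, _ = classify_deciles(v)
        counts = np.bincount(deciles, minlength=11)[1:]
        assert counts.min() >= 95 and counts.max() <= 105

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(6)
        v = rng.lognormal(size=237)
        got, _ = classify_deciles(v)
        assert list(got) == oracle.deciles(list(v))

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=300)
        d1, _ = classify_deciles(v)
        d2, _ = classify_deciles(np.exp(v))
        assert (d1 == d2).all()

    def test_ties_share_a_decile(self):
        v = np.array([1.0] * 50 + [2.0] * 50)
        deciles, _ = classify_deciles(v)
        assert len(set(deciles[:50])) == 1
        assert len(set(deciles[50:])) == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            classify_deciles(np.arange(9.0))


class TestIdw:
    def test_exact_hit_returns_sample_value(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        out = idw_interpolate(xy, [7.0, 1.0, 3.0], [[0.0, 0.0]], k=3)
        assert out[0] == 7.0

    def test_two_equidistant_neighbours_average(self):
        xy = np.array([[-1.0, 0.0], [1.0, 0.0]])
        out = idw_interpolate(xy, [1.0, 3.0], [[0.0, 0.0]], k=2)
        assert out[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_knn(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, size=(40, 2))
        v = rng.normal(size=40)
        q = rng.uniform(0, 100, size=(5, 2))
        got = idw_interpolate(xy, v, q, k=12, power=2.0)
        for i, qi in enumerate(q):
            expected = oracle.idw(
                [tuple(p) for p in xy], list(v), tuple(qi), k=12, power=2.0
            )
            assert got[i] == pytest.approx(expected, rel=1e-9)

    def test_output_within_neighbour_range(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 10, size=(30, 2))
        v = rng.normal(size=30)
        out = idw_interpolate(xy, v, rng.uniform(0, 10, size=(20, 2)), k=12)
        assert (out >= v.min()).all() and (out <= v.max()).all()

    def test_fewer_samples_than_k_warns_and_uses_all(self, caplog):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]])
        with caplog.at_level("WARNING"):
            out = idw_interpolate(xy, [1.0, 3.0], [[0.5, 0.0]], k=12)
        assert out[0] == pytest.approx(2.0)
        assert any("neighbours" in r.message for r in caplog.records)

    def test_default_grid_resolution(self):
        grid = interpolation_grid((0, 0, 300, 400))
        # default cell = diagonal/200 = 2.5 map units
        assert grid.shape[1] == 2
        xs = np.unique(grid[:, 0])
        assert xs[1] - xs[0] == pytest.approx(2.5)


class TestAggregateScale:
    def test_single_member_identity(self):
        idx = pd.Series({"u1": 3.0})
        out = aggregate_scale(idx, {"u1": "A"})
        assert out["A"] == 3.0

    def test_plain_mean(self):
        idx = pd.Series({"u1": 1.0, "u2": 3.0})
        out = aggregate_scale(idx, {"u1": "A", "u2": "A"})
        assert out["A"] == 2.0

    def test_population_weighted_mean(self):
        idx = pd.Series({"u1": 1.0, "u2": 3.0})
        pops = pd.Series({"u1": 10.0, "u2": 30.0})
        out = aggregate_scale(idx, {"u1": "A", "u2": "A"},
                              mode="population_weighted_mean", populations=pops)
        assert out["A"] == pytest.approx(2.5)

    def test_unmapped_unit_rejected(self):
        idx = pd.Series({"u1": 1.0, "u2": 3.0})
        with pytest.raises(ValueError, match="u2"):
            aggregate_scale(idx, {"u1": "A"})
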