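"""Fractional ranks, the concentration index, its SE, curve and pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogineq import (
    ConcentrationIndex,
    ConfigError,
    RankedSample,
    UndefinedIndexError,
    bootstrap_rci_se,
    concentration_curve,
    fractional_ranks,
    pool_rubin,
    rci,
    rci_se_delta,
)


def brute_force_rci(y, ranks, w=None):
    """Independent covariance-form oracle: 2 cov_w(y, R) / mean_w(y)."""
    y = np.asarray(y, float)
    r = np.asarray(ranks, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    w = w / w.sum()
    ybar = float(np.sum(w * y))
    rbar = float(np.sum(w * r))
    cov = float(np.sum(w * (y - ybar) * (r - rbar)))
    return 2.0 * cov / ybar


class TestFractionalRanks:
    def test_equal_weights(self):
        assert np.allclose(fractional_ranks([10, 20, 30, 40]), [0.125, 0.375, 0.625, 0.875])

    def test_unequal_weights_hand_computed(self):
        # normalized weights (0.25, 0.75): ranks 0.125 and 0.25 + 0.375
        assert np.allclose(fractional_ranks([1.0, 2.0], [1.0, 3.0]), [0.125, 0.625])

    def test_returned_in_original_row_order(self):
        assert np.allclose(fractional_ranks([40, 10, 30, 20]), [0.875, 0.125, 0.625, 0.375])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ConfigError):
            fractional_ranks([1, 2], [1.0, 0.0])

    @given(
        x=st.lists(st.floats(-50, 50), min_size=2, max_size=30),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=100, deadline=None)
    def test_weighted_mean_rank_is_half(self, x, seed):
        w = np.random.default_rng(seed).uniform(0.1, 5.0, size=len(x))
        for ties in ("stable", "average"):
            r = fractional_ranks(np.array(x), w, ties=ties)
            assert np.sum(w / w.sum() * r) == pytest.approx(0.5, abs=1e-12)

    def test_tie_averaging_assigns_common_rank(self):
        x = [1.0, 1.0, 2.0]
        r = fractional_ranks(x, ties="average")
        assert r[0] == r[1]
        r_stable = fractional_ranks(x, ties="stable")
        assert r_stable[0] != r_stable[1]


class TestRci:
    def test_constant_outcome_has_no_inequality(self):
        s = RankedSample.from_data(np.full(50, 2.0), np.arange(50))
        assert rci(s) == pytest.approx(0.0, abs=1e-14)

    def test_outcome_equal_to_rank_approaches_one_third(self):
        n = 100_000
        ranking = np.arange(n)
        s = RankedSample.from_data((np.arange(n) + 0.5) / n, ranking)
        assert rci(s) == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_pro_poor_outcome_is_negative(self):
        n = 200
        ranking = np.arange(n, dtype=float)
        y = n - np.arange(n, dtype=float)  # positive, decreasing in rank
        assert rci(RankedSample.from_data(y, ranking)) < 0

    def test_zero_mean_outcome_rejected(self):
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        with pytest.raises(UndefinedIndexError):
            rci(RankedSample.from_data(y, np.arange(4)))

    def test_scale_invariance(self, rng):
        """The relative index is invariant to rescaling y by any c != 0: the
        factor cancels between the covariance and the mean.  (Sign flips come
        from recentring, e.g. negating a positive-mean outcome's deviations,
        not from rescaling.)"""
        y = rng.uniform(0.5, 2.0, 100)
        x = rng.normal(size=100)
        w = rng.uniform(0.5, 2.0, 100)
        base = rci(RankedSample.from_data(y, x, w))
        assert rci(RankedSample.from_data(3.7 * y, x, w)) == pytest.approx(base, abs=1e-12)
        assert rci(RankedSample.from_data(-2.0 * y, x, w)) == pytest.approx(base, abs=1e-12)
        # recentring that flips the deviations around the mean flips the index
        mu = np.sum(w / w.sum() * y)
        reflected = 2 * mu - y
        assert rci(RankedSample.from_data(reflected, x, w)) == pytest.approx(-base, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        y = rng.uniform(0.5, 2.0, 100)
        x = rng.normal(size=100)
        w = rng.uniform(0.5, 2.0, 100)
        a = RankedSample.from_data(y, x, w)
        b = RankedSample.from_data(y, np.exp(x / 2.0), w)  # strictly increasing
        assert np.allclose(a.rank, b.rank)
        assert rci(a) == pytest.approx(rci(b), abs=1e-14)
        assert rci_se_delta(a) == pytest.approx(rci_se_delta(b), abs=1e-14)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_matches_brute_force_covariance_oracle(self, n, rng):
        for _ in range(5):
            y = rng.uniform(0.2, 3.0, n)
            x = rng.normal(size=n)
            s = RankedSample.from_data(y, x)
            assert rci(s) == pytest.approx(brute_force_rci(y, s.rank), abs=1e-12)


class TestDeltaSe:
    def test_null_coverage_near_nominal(self, rng):
        """95% CI covers 0 for ~95% of null replicates (quick version)."""
        cover = 0
        reps = 300
        for _ in range(reps):
            y = rng.normal(1.0, 0.3, 300)
            est = ConcentrationIndex().fit(y, rng.normal(size=300))
            cover += est.ci_low_ <= 0.0 <= est.ci_high_
        assert 0.92 <= cover / reps <= 0.98

    def test_se_shrinks_like_inverse_sqrt_n(self):
        means = {}
        for n in (400, 1600):
            vals = []
            for r in range(150):
                g = np.random.default_rng([n, r])
                vals.append(
                    rci_se_delta(
                        RankedSample.from_data(g.normal(1, 0.3, n), g.normal(size=n))
                    )
                )
            means[n] = np.mean(vals)
        assert means[400] / means[1600] == pytest.approx(2.0, rel=0.15)

    def test_constant_outcome_null_index_formula(self):
        s = RankedSample.from_data(np.full(20, 1.0), np.arange(20))
        se = rci_se_delta(s)
        assert np.isfinite(se) and se >= 0.0
        assert rci(s) == pytest.approx(0.0, abs=1e-14)

    def test_bootstrap_agrees_with_delta_in_order_of_magnitude(self, rng):
        y = rng.normal(1.0, 0.3, 400)
        x = rng.normal(size=400)
        s = RankedSample.from_data(y, x)
        delta = rci_se_delta(s)
        boot = bootstrap_rci_se(s, n_boot=200, seed=1)
        assert 0.5 < boot / delta < 2.0


class TestCurve:
    def test_constant_outcome_lies_on_diagonal(self):
        s = RankedSample.from_data(np.full(40, 3.0), np.arange(40))
        pts = concentration_curve(s)
        assert np.allclose(pts[:, 0], pts[:, 1], atol=1e-12)

    def test_endpoints(self, rng):
        s = RankedSample.from_data(rng.uniform(1, 2, 25), rng.normal(size=25))
        pts = concentration_curve(s)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)

    def test_twice_area_between_curve_and_diagonal_equals_rci(self, rng):
        y = rng.uniform(0.5, 2.0, 2000)
        x = y + rng.normal(0, 0.5, 2000)  # induce a gradient
        s = RankedSample.from_data(y, x)
        pts = concentration_curve(s)
        area = np.trapezoid(pts[:, 0] - pts[:, 1], pts[:, 0])
        assert 2.0 * area == pytest.approx(rci(s), abs=5e-3)


class TestPoolRubin:
    def test_single_imputation_falls_back_to_within_variance(self):
        res = pool_rubin([0.3], [0.05])
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.05)
        assert res.ci_low == pytest.approx(0.3 - 1.959964 * 0.05, abs=1e-5)

    def test_identical_estimates_have_zero_between_variance(self):
        res = pool_rubin([0.2] * 8, [0.04] * 8)
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.04)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(5)
        est = rng.normal(0.25, 0.03, 20)
        ses = rng.uniform(0.02, 0.05, 20)
        res = pool_rubin(est, ses, n_complete=500)
        m = 20
        wbar = np.mean(ses**2)
        b = np.var(est, ddof=1)
        total = wbar + (1 + 1 / m) * b
        assert res.estimate == pytest.approx(est.mean())
        assert res.se == pytest.approx(np.sqrt(total))
        # Barnard-Rubin df widens the interval relative to the normal one
        assert res.ci_high - res.ci_low >= 2 * 1.959963 * res.se - 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            pool_rubin([], [])
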