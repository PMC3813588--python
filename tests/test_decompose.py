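"""Wagstaff decomposition: regression, contributor indices, additivity."""

import numpy as np
import pandas as pd
import pytest

from cogineq import (
    GeneratorConfig,
    RankedSample,
    SingularDesignError,
    UndefinedIndexError,
    WagstaffDecomposition,
    contribution_share,
    contributor_ci,
    decompose,
    format_table3,
    generate_survey,
    rci,
    weighted_ols,
)
from cogineq.model import build_design


def _random_problem(rng, n=200, p=3):
    X = pd.DataFrame(
        rng.normal(1.0, 0.5, size=(n, p)), columns=[f"x{j}" for j in range(p)]
    )
    y = 0.5 + X.to_numpy() @ rng.uniform(-1, 1, p) + rng.normal(0, 0.3, n) + 1.0
    ranking = X["x0"].to_numpy() + rng.normal(0, 0.5, n)
    w = rng.uniform(0.5, 2.0, n)
    return y, X, ranking, w


class TestWeightedOls:
    def test_noiseless_recovery_is_exact(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = 1.5 + X @ np.array([2.0, -1.0, 0.5])
        fit = weighted_ols(y.to_numpy(), X, rng.uniform(0.5, 2, 100))
        assert fit.intercept == pytest.approx(1.5, abs=1e-10)
        assert np.allclose(fit.betas, [2.0, -1.0, 0.5], atol=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_equal_weights_match_normal_equations_oracle(self, rng):
        y, X, _, _ = _random_problem(rng)
        fit = weighted_ols(y, X)
        Xc = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta_ne = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)  # independent solve
        assert fit.intercept == pytest.approx(beta_ne[0], abs=1e-8)
        assert np.allclose(fit.betas.to_numpy(), beta_ne[1:], atol=1e-8)

    def test_duplicated_column_raises_named_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        X["dup"] = X["a"]
        with pytest.raises(SingularDesignError, match="dup|a"):
            weighted_ols(rng.normal(size=50), X)

    def test_residuals_have_zero_weighted_mean(self, rng):
        y, X, _, w = _random_problem(rng)
        fit = weighted_ols(y, X, w)
        assert np.sum(w / w.sum() * fit.residuals) == pytest.approx(0.0, abs=1e-8)


class TestContributorCi:
    def test_top_half_indicator_is_half(self):
        n = 10_000
        ranking = np.arange(n, dtype=float)
        s = RankedSample.from_data(np.ones(n), ranking)
        x = (ranking >= n / 2).astype(float)
        assert contributor_ci(x, s) == pytest.approx(0.5, abs=1e-3)

    def test_constant_contributor_is_zero(self, rng):
        s = RankedSample.from_data(rng.uniform(1, 2, 30), rng.normal(size=30))
        assert contributor_ci(np.full(30, 1.0), s) == 0.0

    def test_pro_poor_indicator_is_negative(self):
        n = 1000
        ranking = np.arange(n, dtype=float)
        s = RankedSample.from_data(np.ones(n), ranking)
        assert contributor_ci((ranking < n / 4).astype(float), s) < 0

    def test_zero_mean_contributor_rejected(self, rng):
        s = RankedSample.from_data(rng.uniform(1, 2, 10), rng.normal(size=10))
        with pytest.raises(UndefinedIndexError):
            contributor_ci(np.r_[np.ones(5), -np.ones(5)], s)


class TestDecompose:
    def test_saturated_model_gives_unit_share(self, rng):
        n = 300
        ranking = rng.normal(size=n)
        y = np.exp(ranking / 3.0) + 1.0  # positive, rank-correlated
        X = pd.DataFrame({"x": y})
        s = RankedSample.from_data(y, ranking)
        res = decompose(weighted_ols(y, X), s, X)
        assert res.table.loc["x", "share"] == pytest.approx(1.0, abs=1e-10)
        assert res.residual_share == pytest.approx(0.0, abs=1e-10)

    def test_additivity_identity_random_inputs(self, rng):
        for _ in range(25):
            y, X, ranking, w = _random_problem(rng)
            est = WagstaffDecomposition().fit(X, y, ranking, w)
            res = est.result_
            assert res.additivity_gap() < 1e-10
            assert res.total_rci == pytest.approx(
                rci(RankedSample.from_data(y, ranking, w)), abs=1e-12
            )
            shares = res.table["share"].sum() + res.residual_share
            assert shares == pytest.approx(1.0, abs=1e-10)

    def test_elasticity_invariant_to_column_rescaling(self, rng):
        y, X, ranking, w = _random_problem(rng)
        a = WagstaffDecomposition().fit(X, y, ranking, w).result_
        X2 = X.copy()
        X2["x1"] = X2["x1"] * 10.0
        b = WagstaffDecomposition().fit(X2, y, ranking, w).result_
        assert b.table.loc["x1", "beta"] == pytest.approx(a.table.loc["x1", "beta"] / 10)
        assert b.table.loc["x1", "elasticity"] == pytest.approx(
            a.table.loc["x1", "elasticity"], abs=1e-10
        )
        assert b.table.loc["x1", "contribution"] == pytest.approx(
            a.table.loc["x1", "contribution"], abs=1e-10
        )

    def test_recovers_generator_betas_within_3_se(self):
        cfg = GeneratorConfig(n_children=20_000, seed=11)
        t = generate_survey(cfg)
        X = build_design(t)
        X["age"] = t["age"].astype(float)
        import statsmodels.api as sm

        fit = sm.WLS(
            t["raw_score"].to_numpy(float),
            sm.add_constant(X.to_numpy()),
            weights=t["weight"].to_numpy(),
        ).fit()
        names = ["const"] + list(X.columns)
        for i, k in enumerate(names):
            if k in cfg.true_betas:
                assert abs(fit.params[i] - cfg.true_betas[k]) <= 3 * fit.bse[i], k

    def test_rank_independent_contributor_contributes_nothing(self, rng):
        n = 5000
        ranking = rng.normal(size=n)
        X = pd.DataFrame(
            {"grad": np.exp(ranking / 3) + rng.normal(0, 0.1, n), "null": rng.uniform(1, 2, n)}
        )
        y = 1.0 + X["grad"] + X["null"] + rng.normal(0, 0.2, n)
        res = WagstaffDecomposition().fit(X, y.to_numpy(), ranking).result_
        assert abs(res.table.loc["null", "ck"]) < 0.05
        assert abs(res.table.loc["null", "share"]) < 0.1 * abs(res.table.loc["grad", "share"])

    def test_ordering_matches_generator_construction(self, zscored_2000):
        t = zscored_2000
        X = build_design(t)
        res = WagstaffDecomposition().fit(
            X, t["z"].to_numpy(), t["log_pce"].to_numpy(), t["weight"].to_numpy()
        ).result_
        shares = res.table["share"]
        # expenditure itself carries the largest share; the strong-gradient
        # strong-beta covariates rank above the null-gradient ones
        assert shares.idxmax() == "log_pce"
        assert shares["improved_sanitation"] > shares["improved_water"]
        assert shares["mother_edu_hs"] > shares["mother_working"]


class TestReportTable:
    def test_printed_share_arithmetic(self):
        # shares recomputed from (elasticity, C_k, total RCI) triples round to
        # the published integer percents
        assert round(100 * contribution_share(0.03, 0.67, 0.29)) == 7
        assert round(100 * contribution_share(0.16, 0.33, 0.29)) == 18
        assert round(100 * contribution_share(0.03, 0.69, 0.29)) == 7

    def test_format_sorts_and_sums_to_100(self, zscored_2000):
        t = zscored_2000
        X = build_design(t)
        res = WagstaffDecomposition().fit(
            X, t["z"].to_numpy(), t["log_pce"].to_numpy(), t["weight"].to_numpy()
        ).result_
        tab = format_table3(res)
        assert tab.index[-1] == "residual"
        pct = tab["contribution_pct"].astype(int)
        body = pct.iloc[:-1]
        assert body.is_monotonic_decreasing
        # rounded signed percents sum to ~100 (rounding slack: half a point/row)
        assert abs(pct.sum() - 100) <= len(pct) * 0.5 + 1
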