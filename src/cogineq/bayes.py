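"""Bayesian weighted linear regression by Gibbs sampling, used to propagate
coefficient uncertainty into decomposition contribution shares.

The model is the conjugate normal-inverse-gamma regression on the weighted
likelihood sum_i w_i (y_i - x_i'beta)^2 / sigma^2 (weights scaled to mean 1
so the effective sample size is n).  The sampler alternates

    beta  | sigma^2, data ~ Normal(Lambda^-1 rhs, Lambda^-1),
           Lambda = X'WX / sigma^2 + P,  rhs = X'Wy / sigma^2 + P m0
    sigma^2 | beta, data ~ InvGamma(a0 + n/2, r0 + SSR_w / 2)

with an isotropic Normal(m0, P^-1) prior on beta (vague by default) and an
InvGamma(a0, r0) prior on sigma^2.  Only beta and sigma^2 are treated as
uncertain downstream: contributor concentration indices, weighted means,
the outcome mean and the ranks are held at their sample values, which
understates rank uncertainty (a documented simplification).

Credible intervals are equal-tail: the 2.5th and 97.5th percentiles of the
per-draw contribution shares, by linear-interpolation order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .concentration import RankedSample, rci
from .decompose import contributor_ci
from .errors import ConfigError, SchemaError, SingularDesignError

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "GibbsLinearRegression",
    "gibbs_regression",
    "contribution_intervals",
]


@dataclass
class McmcConfig:
    """Gibbs-sampler settings (vague-prior defaults)."""

    n_draws: int = 5000
    burn_in: int = 1000
    seed: int = 0
    prior_beta_mean: np.ndarray | None = None  # None -> zeros
    prior_beta_precision: float = 1e-6
    prior_sigma_shape: float = 1e-3
    prior_sigma_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ConfigError(f"n_draws must be > 0, got {self.n_draws}")
        if self.burn_in < 0:
            raise ConfigError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.prior_beta_precision < 0:
            raise ConfigError("prior_beta_precision must be >= 0")
        if self.prior_sigma_shape <= 0 or self.prior_sigma_rate <= 0:
            raise ConfigError("prior_sigma_shape and prior_sigma_rate must be > 0")


@dataclass
class PosteriorDraws:
    """Retained posterior draws; ``betas`` columns are const + contributors."""

    betas: pd.DataFrame
    sigma2: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.betas.to_numpy())) or not np.all(
            np.isfinite(self.sigma2)
        ):
            raise ConfigError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return len(self.betas)


class GibbsLinearRegression(BaseEstimator, RegressorMixin):
    """Conjugate Gibbs sampler for weighted linear regression.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    coef_ : posterior-mean contributor coefficients (Series)
    intercept_ : posterior-mean intercept
    sigma2_mean_ : posterior-mean error variance
    """

    def __init__(
        self,
        n_draws: int = 5000,
        burn_in: int = 1000,
        seed: int = 0,
        prior_beta_mean=None,
        prior_beta_precision: float = 1e-6,
        prior_sigma_shape: float = 1e-3,
        prior_sigma_rate: float = 1e-3,
    ):
        self.n_draws = n_draws
        self.burn_in = burn_in
        self.seed = seed
        self.prior_beta_mean = prior_beta_mean
        self.prior_beta_precision = prior_beta_precision
        self.prior_sigma_shape = prior_sigma_shape
        self.prior_sigma_rate = prior_sigma_rate

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_draws=self.n_draws,
            burn_in=self.burn_in,
            seed=self.seed,
            prior_beta_mean=self.prior_beta_mean,
            prior_beta_precision=self.prior_beta_precision,
            prior_sigma_shape=self.prior_sigma_shape,
            prior_sigma_rate=self.prior_sigma_rate,
        )

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "GibbsLinearRegression":
        cfg = self._config()
        y = np.asarray(y, dtype=float)
        if X.isna().to_numpy().any() or np.isnan(y).any():
            raise SchemaError("gibbs_regression requires complete cases")
        names = ["const"] + list(X.columns)
        n = len(y)
        Xc = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        p = Xc.shape[1]
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if np.any(w <= 0):
            raise ConfigError("weights must be strictly positive")
        w = w * n / w.sum()  # mean-1 weights: effective sample size n

        XtWX = Xc.T @ (w[:, None] * Xc)
        XtWy = Xc.T @ (w * y)
        m0 = np.zeros(p) if cfg.prior_beta_mean is None else np.asarray(
            cfg.prior_beta_mean, dtype=float
        )
        if m0.shape != (p,):
            raise ConfigError(
                f"prior_beta_mean must have length {p} (const + contributors), got {m0.shape}"
            )
        P = cfg.prior_beta_precision * np.eye(p)

        rng = np.random.default_rng(cfg.seed)
        # initialize sigma^2 at the weighted LS residual variance
        try:
            beta = np.linalg.solve(XtWX + P, XtWy + P @ m0)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"posterior precision is singular: {exc}") from exc
        resid = y - Xc @ beta
        sigma2 = max(float(np.sum(w * resid**2) / max(n - p, 1)), 1e-12)

        total = cfg.burn_in + cfg.n_draws
        beta_draws = np.empty((cfg.n_draws, p))
        sigma2_draws = np.empty(cfg.n_draws)
        for it in range(total):
            lam = XtWX / sigma2 + P
            try:
                chol = np.linalg.cholesky(lam)
            except np.linalg.LinAlgError as exc:
                raise SingularDesignError(
                    f"posterior precision is singular: {exc}"
                ) from exc
            mean = np.linalg.solve(lam, XtWy / sigma2 + P @ m0)
            zdraw = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, zdraw)
            resid = y - Xc @ beta
            shape = cfg.prior_sigma_shape + 0.5 * n
            rate = cfg.prior_sigma_rate + 0.5 * float(np.sum(w * resid**2))
            sigma2 = rate / rng.gamma(shape)
            if it >= cfg.burn_in:
                beta_draws[it - cfg.burn_in] = beta
                sigma2_draws[it - cfg.burn_in] = sigma2

        self.draws_ = PosteriorDraws(
            betas=pd.DataFrame(beta_draws, columns=names),
            sigma2=sigma2_draws,
            feature_names=names[1:],
        )
        post_mean = self.draws_.betas.mean()
        self.intercept_ = float(post_mean["const"])
        self.coef_ = post_mean.drop("const")
        self.sigma2_mean_ = float(sigma2_draws.mean())
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept_ + X[list(self.coef_.index)].to_numpy() @ self.coef_.to_numpy()


def gibbs_regression(y, X: pd.DataFrame, w=None, config: McmcConfig | None = None) -> PosteriorDraws:
    """Functional wrapper returning the posterior draws."""
    cfg = config or McmcConfig()
    est = GibbsLinearRegression(
        n_draws=cfg.n_draws,
        burn_in=cfg.burn_in,
        seed=cfg.seed,
        prior_beta_mean=cfg.prior_beta_mean,
        prior_beta_precision=cfg.prior_beta_precision,
        prior_sigma_shape=cfg.prior_sigma_shape,
        prior_sigma_rate=cfg.prior_sigma_rate,
    )
    est.fit(X, y, sample_weight=w)
    return est.draws_


def contribution_intervals(
    draws: PosteriorDraws,
    sample: RankedSample,
    X: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Equal-tail credible intervals of per-contributor contribution shares.

    Per draw the elasticity eta_k = beta_k xbar_k / mu and the share
    eta_k C_k / C are recomputed with C_k, xbar_k, mu and the total index C
    held at their sample values.  Returns a DataFrame indexed by contributor
    with columns share (posterior mean), lower and upper.
    """
    names = draws.feature_names
    if list(X.columns) != names:
        raise SchemaError(
            f"design columns {list(X.columns)} do not match draw columns {names}"
        )
    mu = sample.mu
    total = rci(sample)
    xbar = sample.w @ X.to_numpy(dtype=float)
    cks = np.array(
        [
            contributor_ci(X[k].to_numpy(dtype=float), sample)
            if np.ptp(X[k].to_numpy(dtype=float)) > 0
            else 0.0
            for k in names
        ]
    )
    beta_draws = draws.betas[names].to_numpy()  # n_draws x k
    share_draws = beta_draws * (xbar * cks) / (mu * total)
    lo = np.percentile(share_draws, 100 * alpha / 2.0, axis=0)
    hi = np.percentile(share_draws, 100 * (1 - alpha / 2.0), axis=0)
    return pd.DataFrame(
        {"share": share_draws.mean(axis=0), "lower": lo, "upper": hi},
        index=pd.Index(names, name="contributor"),
    )
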