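"""Regression-based (Wagstaff) decomposition of the concentration index.

With a linear outcome model y_i = alpha + sum_k beta_k x_ik + eps_i fitted by
weighted least squares, the outcome RCI decomposes exactly as

    C = sum_k eta_k C_k + GC_eps / mu,     eta_k = beta_k * xbar_k / mu

where C_k is the contributor's own concentration index over the expenditure
ranks, xbar_k its weighted mean, and GC_eps = 2 sum_i w_i eps_i (R_i - 1/2)
the generalized (unscaled) concentration index of the residuals.  The
identity is algebraic: it holds to machine precision for any fitted model
because WLS residuals are weight-orthogonal to the design and the weighted
mean rank is exactly 1/2.  Each contributor's share is its term divided by
the total index; shares are signed and sum to 1 with the residual included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.base import BaseEstimator

from .concentration import RankedSample, rci
from .errors import ConfigError, SchemaError, SingularDesignError, UndefinedIndexError

__all__ = [
    "RegressionFit",
    "DecompositionResult",
    "weighted_ols",
    "contributor_ci",
    "WagstaffDecomposition",
    "decompose",
    "contribution_share",
    "format_table3",
]

_RANK_RTOL = 1e-8


@dataclass
class RegressionFit:
    """Weighted-least-squares fit of the outcome model."""

    betas: pd.Series
    intercept: float
    residuals: np.ndarray
    xbar: pd.Series

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.betas.index].to_numpy() @ self.betas.to_numpy()


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise a named error listing (near-)collinear columns via pivoted QR."""
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps * 1e2
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if design.shape[1] > len(diag):
        bad += [names[p] for p in piv[len(diag):]]
    if bad:
        raise SingularDesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def weighted_ols(y, X: pd.DataFrame, w=None) -> RegressionFit:
    """Fit y on X (plus intercept) minimizing sum_i w_i (y_i - a - x_i'b)^2."""
    y = np.asarray(y, dtype=float)
    if X.isna().to_numpy().any() or np.isnan(y).any():
        raise SchemaError("weighted_ols requires complete cases; drop missing rows first")
    n, p = X.shape
    if n <= p + 1:
        raise ConfigError(f"need n > {p + 1} rows to fit {p} contributors, got n={n}")
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ConfigError("weights must be strictly positive")
    names = list(X.columns)
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True, has_constant="add")
    _check_full_rank(np.sqrt(w)[:, None] * Xc, ["const"] + names)
    fit = sm.WLS(y, Xc, weights=w).fit()
    wn = w / w.sum()
    return RegressionFit(
        betas=pd.Series(fit.params[1:], index=names),
        intercept=float(fit.params[0]),
        residuals=np.asarray(fit.resid, dtype=float),
        xbar=pd.Series(wn @ X.to_numpy(dtype=float), index=names),
    )


def contributor_ci(x_k, sample: RankedSample) -> float:
    """Concentration index of one contributor over the same expenditure ranks.

    A constant contributor has index 0 by convention; a zero-mean contributor
    has no relative index.
    """
    x = np.asarray(x_k, dtype=float)
    xbar = float(sample.w @ x)
    # numerically-zero mean relative to the variable's scale
    if abs(xbar) < 1e-12 * max(1.0, float(np.max(np.abs(x), initial=0.0))):
        raise UndefinedIndexError("contributor has zero weighted mean; RCI undefined")
    if np.ptp(x) == 0.0:
        return 0.0
    return float(2.0 / xbar * np.sum(sample.w * x * (sample.rank - 0.5)))


@dataclass
class DecompositionResult:
    """Per-contributor decomposition terms for one survey round.

    ``table`` is indexed by contributor with columns beta, xbar, elasticity,
    ck, contribution and share (share = contribution / total_rci; NaN when
    the total index is 0).
    """

    table: pd.DataFrame
    residual_contribution: float
    total_rci: float
    mu: float
    n: int
    label: str = ""

    @property
    def residual_share(self) -> float:
        return self.residual_contribution / self.total_rci if self.total_rci else float("nan")

    @property
    def contributors(self) -> list[str]:
        return list(self.table.index)

    def additivity_gap(self) -> float:
        """|sum of terms + residual - total RCI|; 0 up to round-off."""
        return abs(self.table["contribution"].sum() + self.residual_contribution - self.total_rci)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "total_rci": self.total_rci,
            "mu": self.mu,
            "n": self.n,
            "residual_contribution": self.residual_contribution,
            "contributors": {
                k: {c: float(self.table.at[k, c]) for c in self.table.columns}
                for k in self.table.index
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "DecompositionResult":
        table = pd.DataFrame.from_dict(d["contributors"], orient="index")
        return cls(
            table=table,
            residual_contribution=float(d["residual_contribution"]),
            total_rci=float(d["total_rci"]),
            mu=float(d["mu"]),
            n=int(d["n"]),
            label=d.get("label", ""),
        )

    @classmethod
    def from_json(cls, text: str) -> "DecompositionResult":
        return cls.from_dict(json.loads(text))


class WagstaffDecomposition(BaseEstimator):
    """Estimator decomposing the outcome RCI into contributor shares.

    Parameters
    ----------
    ties : {"stable", "average"}
        Tie handling for the expenditure ranks.

    Attributes (after ``fit``)
    --------------------------
    fit_ : RegressionFit
    sample_ : RankedSample
    result_ : DecompositionResult
    """

    def __init__(self, ties: str = "stable"):
        self.ties = ties

    def fit(self, X: pd.DataFrame, y, ranking, sample_weight=None, label: str = "") -> "WagstaffDecomposition":
        y = np.asarray(y, dtype=float)
        sample = RankedSample.from_data(y, ranking, sample_weight, ties=self.ties)
        fit = weighted_ols(y, X, sample.w)
        self.fit_ = fit
        self.sample_ = sample
        self.result_ = decompose(fit, sample, X, label=label)
        return self

    @property
    def contributions_(self) -> pd.Series:
        return self.result_.table["contribution"]

    @property
    def shares_(self) -> pd.Series:
        return self.result_.table["share"]


def decompose(
    fit: RegressionFit, sample: RankedSample, X: pd.DataFrame, label: str = ""
) -> DecompositionResult:
    """Assemble per-contributor elasticities, indices and shares from a fit."""
    mu = sample.mu
    if mu == 0:
        raise UndefinedIndexError("outcome mean is zero; decomposition undefined")
    total = rci(sample)
    rows = {}
    for k in fit.betas.index:
        xk = X[k].to_numpy(dtype=float)
        ck = contributor_ci(xk, sample) if np.ptp(xk) > 0 else 0.0
        eta = fit.betas[k] * fit.xbar[k] / mu
        contribution = eta * ck
        rows[k] = {
            "beta": float(fit.betas[k]),
            "xbar": float(fit.xbar[k]),
            "elasticity": float(eta),
            "ck": float(ck),
            "contribution": float(contribution),
        }
    gc_eps = 2.0 * float(np.sum(sample.w * fit.residuals * (sample.rank - 0.5)))
    residual_contribution = gc_eps / mu
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["share"] = table["contribution"] / total if total != 0 else np.nan
    return DecompositionResult(
        table=table,
        residual_contribution=residual_contribution,
        total_rci=total,
        mu=mu,
        n=sample.n,
        label=label,
    )


def contribution_share(elasticity: float, ck: float, total_rci: float) -> float:
    """Share (fraction of the total index) implied by one contributor's
    elasticity and concentration index: eta_k * C_k / C."""
    if total_rci == 0:
        raise UndefinedIndexError("total RCI is zero; shares undefined")
    return elasticity * ck / total_rci


def format_table3(
    result: DecompositionResult, cis: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Report table: one row per contributor sorted by descending share.

    Columns use the conventional printed precision (2 decimals for beta,
    elasticity and concentration index; integer signed percents for the
    contribution and its CI bounds); the residual row comes last.
    """
    tab = result.table.sort_values("share", ascending=False)
    out = pd.DataFrame(
        {
            "beta": tab["beta"].round(2),
            "elasticity": tab["elasticity"].round(2),
            "concentration_index": tab["ck"].round(2),
            "contribution_pct": (tab["share"] * 100).round(0).astype(int),
        },
        index=tab.index,
    )
    if cis is not None:
        out["ci_low_pct"] = (cis.loc[tab.index, "lower"] * 100).round(0).astype(int)
        out["ci_high_pct"] = (cis.loc[tab.index, "upper"] * 100).round(0).astype(int)
    residual = {c: "" for c in out.columns}
    residual["contribution_pct"] = int(round(result.residual_share * 100))
    out.loc["residual"] = residual
    return out
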