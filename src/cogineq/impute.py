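"""Chained-equations multiple imputation for the RCI path.

A deliberately transparent regression-switching sampler: each incomplete
column is regressed on all other analysis variables (linear model on the
currently completed data), and its missing cells are redrawn from the
predictive distribution — prediction plus a Gaussian noise draw for
continuous columns, a latent-score draw thresholded at 0.5 for binary
columns, and a latent-score draw rounded onto the ordinal code range for
the three-level education categories.  Initial fills are random draws from
each column's observed empirical distribution; observed cells are never
altered.  Imputation runs within survey round, and is used only for RCI
estimation (never for the decomposition), with Rubin's rules pooling the
per-imputation estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .concentration import ConcentrationIndex, RCIResult, pool_rubin
from .errors import ConfigError, SchemaError, UnimputableColumnError
from .model import CATEGORICAL_COLUMNS, EDU_LEVELS

__all__ = ["ImputationConfig", "ChainedImputer", "chained_impute", "rci_with_imputation"]


@dataclass
class ImputationConfig:
    """Settings for chained-equations multiple imputation."""

    m: int = 20
    cycles: int = 50
    seed: int = 0
    exclude_col: str | None = None  # boolean column: True rows dropped first

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError(f"m must be >= 1, got {self.m}")
        if self.cycles < 1:
            raise ConfigError(f"cycles must be >= 1, got {self.cycles}")


def _is_binary(values: np.ndarray) -> bool:
    return set(np.unique(values)).issubset({0.0, 1.0})


class ChainedImputer(BaseEstimator):
    """Multiple imputation by chained equations over survey columns.

    Parameters
    ----------
    m, cycles, seed : int
        Number of completed datasets, regression-switching sweeps per
        dataset, and random seed.
    round_col : str or None
        Imputation is run independently within each level of this column.
    exclude_cols : tuple
        Columns never used as predictors nor imputed (the sampling weight
        by default; the round label is excluded automatically).
    """

    def __init__(
        self,
        m: int = 20,
        cycles: int = 50,
        seed: int = 0,
        round_col: str | None = "round",
        exclude_cols: tuple = ("weight",),
    ):
        self.m = m
        self.cycles = cycles
        self.seed = seed
        self.round_col = round_col
        self.exclude_cols = exclude_cols

    # --- internal ------------------------------------------------------
    def _encode(self, table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        """Numeric working copy: education levels -> ordinal codes 0/1/2."""
        work = pd.DataFrame(index=table.index)
        cols = []
        for c in table.columns:
            if c == self.round_col or c in self.exclude_cols:
                continue
            if c in CATEGORICAL_COLUMNS:
                codes = table[c].astype(object).map(
                    {lvl: i for i, lvl in enumerate(EDU_LEVELS)}
                )
                bad = table[c].notna() & codes.isna()
                if bad.any():
                    raise SchemaError(f"{c} has undeclared levels")
                work[c] = codes.astype(float)
            else:
                work[c] = pd.to_numeric(table[c], errors="coerce").astype(float)
            cols.append(c)
        return work, cols

    def _impute_group(self, work: pd.DataFrame, cols: list[str], rng) -> pd.DataFrame:
        observed = work.notna()
        incomplete = [c for c in cols if not observed[c].all()]
        for c in incomplete:
            if not observed[c].any():
                raise UnimputableColumnError(f"column {c!r} has no observed values")
        filled = work.copy()
        # initial fill: draw from the observed empirical distribution
        for c in incomplete:
            obs_vals = work.loc[observed[c], c].to_numpy()
            n_miss = int((~observed[c]).sum())
            filled.loc[~observed[c], c] = rng.choice(obs_vals, size=n_miss, replace=True)
        col_kind = {}
        for c in incomplete:
            vals = work.loc[observed[c], c].to_numpy()
            if c in CATEGORICAL_COLUMNS:
                col_kind[c] = "ordinal"
            elif _is_binary(vals):
                col_kind[c] = "binary"
            else:
                col_kind[c] = "continuous"
        for _ in range(self.cycles):
            for c in incomplete:
                others = [o for o in cols if o != c]
                Xall = filled[others].to_numpy()
                obs_mask = observed[c].to_numpy()
                Xobs = np.column_stack([np.ones(obs_mask.sum()), Xall[obs_mask]])
                yobs = work.loc[observed[c], c].to_numpy()
                coef, *_ = np.linalg.lstsq(Xobs, yobs, rcond=None)
                resid = yobs - Xobs @ coef
                dof = max(len(yobs) - len(coef), 1)
                sigma = float(np.sqrt(np.sum(resid**2) / dof))
                Xmis = np.column_stack([np.ones((~obs_mask).sum()), Xall[~obs_mask]])
                latent = Xmis @ coef + rng.normal(0.0, sigma, size=len(Xmis))
                if col_kind[c] == "binary":
                    drawn = (latent > 0.5).astype(float)
                elif col_kind[c] == "ordinal":
                    drawn = np.clip(np.rint(latent), 0, len(EDU_LEVELS) - 1)
                else:
                    drawn = latent
                filled.loc[~observed[c], c] = drawn
        return filled

    # --- public --------------------------------------------------------
    def fit_transform(self, table: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        """Return ``m`` completed copies of ``table`` (observed cells intact)."""
        work, cols = self._encode(table)
        groups: list[np.ndarray]
        if self.round_col is not None and self.round_col in table.columns:
            groups = [
                table.index[table[self.round_col] == lvl].to_numpy()
                for lvl in pd.unique(table[self.round_col])
            ]
        else:
            groups = [table.index.to_numpy()]
        completed: list[pd.DataFrame] = []
        for i in range(self.m):
            rng = np.random.default_rng([self.seed, i])
            filled = work.copy()
            for idx in groups:
                filled.loc[idx] = self._impute_group(work.loc[idx], cols, rng)
            out = table.copy()
            for c in cols:
                if c in CATEGORICAL_COLUMNS:
                    decoded = filled[c].round().astype(int).map(dict(enumerate(EDU_LEVELS)))
                    out[c] = decoded.astype(object)
                elif (table[c].dtype.kind in "iu") or _is_binary(
                    work.loc[work[c].notna(), c].to_numpy()
                ):
                    out[c] = filled[c].round().astype(table[c].dtype if table[c].notna().all() else float)
                else:
                    out[c] = filled[c]
            completed.append(out)
        self.n_imputations_ = self.m
        return completed

    fit = fit_transform  # sklearn-style alias; the product is the dataset list


def chained_impute(table: pd.DataFrame, config: ImputationConfig) -> list[pd.DataFrame]:
    """Run MICE with ``config``; applies the exclusion rule first."""
    if config.exclude_col is not None:
        if config.exclude_col not in table.columns:
            raise SchemaError(f"exclusion column {config.exclude_col!r} not in table")
        table = table.loc[~table[config.exclude_col].astype(bool)].copy()
        table = table.drop(columns=[config.exclude_col])
    imputer = ChainedImputer(m=config.m, cycles=config.cycles, seed=config.seed)
    return imputer.fit_transform(table)


def rci_with_imputation(
    table: pd.DataFrame,
    config: ImputationConfig,
    *,
    outcome: str = "z",
    ranking: str = "log_pce",
    weight: str = "weight",
    ties: str = "stable",
) -> RCIResult:
    """Pooled RCI over ``m`` imputed datasets via Rubin's rules.

    Computes the index and its Delta-method SE on each completed dataset and
    pools; with no missingness every completed dataset equals the input and
    the pooled result is the complete-data result.
    """
    completed = chained_impute(table, config)
    estimates, ses = [], []
    mu = float("nan")
    for comp in completed:
        est = ConcentrationIndex(ties=ties).fit(
            comp[outcome].to_numpy(dtype=float),
            comp[ranking].to_numpy(dtype=float),
            comp[weight].to_numpy(dtype=float),
        )
        estimates.append(est.estimate_)
        ses.append(est.se_)
        mu = est.mu_
    return pool_rubin(estimates, ses, n_complete=len(completed[0]), mu=mu)
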