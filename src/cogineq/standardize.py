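"""Age-specific z-scores of the raw cognitive score.

The raw 0-12 score is skewed, so per (round, age) cell the mean and SD are
recovered from the cell's minimum, median, maximum and size with the Hozo
estimator rather than computed as plain moments, and the z-score is
(raw - est_mean) / est_sd.  Cells are integer years of age within survey
round; sexes are pooled.  Min/median/max are order statistics, so sampling
weights play no role in the summaries.

By default the transformer applies the basic Hozo formulas at every cell
size — mean (a + 2m + b)/4 and SD (b - a)/4 (the tiny-n exact-variance
formula below n = 15) — rather than switching to the median / range-6 rules
at large n.  On left-skewed scores the formula mean sits below the median,
so the resulting z-scores have a positive mean and the mean-normalized
concentration index downstream stays well defined; the median branch would
drive the z mean to ~0 and make the relative index degenerate.  The branch
thresholds are parameters, so the published large-n recommendations are one
setting away.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import hozo
from .errors import DegenerateCellError, SchemaError

__all__ = ["AgeZScorer", "fit_zscore_model", "apply_zscore"]


class AgeZScorer(BaseEstimator, TransformerMixin):
    """Transformer adding an age-standardized z-score column.

    Parameters
    ----------
    score_col, age_col, round_col : str
        Column names of the raw score, integer age and survey round.
    z_col : str
        Name of the added column.
    mean_formula_max_n, sd_formula_max_n, sd_range4_max_n : int
        Sample-size branch thresholds of the Hozo mean/SD rules.

    Attributes
    ----------
    cells_ : dict[(round, age) -> (est_mean, est_sd)]
        Fitted per-cell moments.
    """

    def __init__(
        self,
        score_col: str = "raw_score",
        age_col: str = "age",
        round_col: str = "round",
        z_col: str = "z",
        mean_formula_max_n: int = 10**9,
        sd_formula_max_n: int = hozo.SD_FORMULA_MAX_N,
        sd_range4_max_n: int = 10**9,
    ):
        self.score_col = score_col
        self.age_col = age_col
        self.round_col = round_col
        self.z_col = z_col
        self.mean_formula_max_n = mean_formula_max_n
        self.sd_formula_max_n = sd_formula_max_n
        self.sd_range4_max_n = sd_range4_max_n

    def fit(self, X: pd.DataFrame, y=None) -> "AgeZScorer":
        for col in (self.score_col, self.age_col, self.round_col):
            if col not in X.columns:
                raise SchemaError(f"column {col!r} not present in table")
        obs = X[[self.score_col, self.age_col, self.round_col]].dropna(
            subset=[self.score_col, self.age_col]
        )
        cells: dict[tuple, tuple[float, float]] = {}
        for (rnd, age), grp in obs.groupby([self.round_col, self.age_col], sort=True):
            scores = grp[self.score_col].to_numpy(dtype=float)
            summ = hozo.HozoSummary(
                a=float(scores.min()),
                m=float(np.median(scores)),
                b=float(scores.max()),
                n=scores.size,
            )
            sd = hozo.hozo_sd(
                summ,
                formula_max_n=self.sd_formula_max_n,
                range4_max_n=self.sd_range4_max_n,
            )
            if sd == 0:
                raise DegenerateCellError(
                    f"cell (round={rnd!r}, age={age}) has zero score spread"
                )
            mean = hozo.hozo_mean(summ, formula_max_n=self.mean_formula_max_n)
            cells[(rnd, int(age))] = (mean, sd)
        self.cells_ = cells
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        z = np.full(len(X), np.nan)
        score = pd.to_numeric(X[self.score_col], errors="coerce").to_numpy(dtype=float)
        age = pd.to_numeric(X[self.age_col], errors="coerce").to_numpy(dtype=float)
        rounds = X[self.round_col].to_numpy(dtype=object)
        observed = ~(np.isnan(score) | np.isnan(age))
        for i in np.flatnonzero(observed):
            key = (rounds[i], int(age[i]))
            if key not in self.cells_:
                raise LookupError(
                    f"no z-score cell for (round={key[0]!r}, age={key[1]}); "
                    "refit on data covering this cell"
                )
            mean, sd = self.cells_[key]
            z[i] = (score[i] - mean) / sd
        out[self.z_col] = z
        return out

    # --- serialization -------------------------------------------------
    def to_json(self, **kwargs) -> str:
        payload = {
            "params": self.get_params(),
            "cells": [
                {"round": rnd, "age": age, "est_mean": m, "est_sd": s}
                for (rnd, age), (m, s) in sorted(self.cells_.items(), key=str)
            ],
        }
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "AgeZScorer":
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.cells_ = {
            (c["round"], int(c["age"])): (float(c["est_mean"]), float(c["est_sd"]))
            for c in payload["cells"]
        }
        return model


def fit_zscore_model(table: pd.DataFrame, **params) -> AgeZScorer:
    """Fit per-(round, age) Hozo moments on the observed scores."""
    return AgeZScorer(**params).fit(table)


def apply_zscore(table: pd.DataFrame, model: AgeZScorer) -> pd.DataFrame:
    """Return a copy of ``table`` with the z-score column added."""
    return model.transform(table)
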