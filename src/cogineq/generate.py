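"""Seeded synthetic household-survey generator.

Emulates a repeated cross-sectional child survey: one row per child with a
12-item cognitive raw score, child/parental/household covariates, log
per-capita expenditure (PCE) as the living-standards variable, and a
positive person sampling weight.  Covariates are generated from models
monotone in the expenditure rank with configurable gradients, so the
socioeconomic structure the downstream inequality analysis assumes (richer
households more likely to have educated parents, improved sanitation, etc.)
is present by construction and its direction is known ground truth.

The raw score is a latent linear index (configured contributor coefficients
plus an age trend plus Gaussian noise) rounded and clipped into 0-12; with
the default knobs the distribution sits above the scale midpoint with a
mild ceiling, i.e. left-skewed, and increases with age.

Missingness is injected MAR: the cell-missingness probability depends only
on always-observed log PCE and age (poorer, younger -> more missing), and
the marginal rate is calibrated to the configured value.  Outcome, age,
log PCE, weight and round are never set missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigError
from .model import CONTRIBUTORS, EDU_LEVELS

__all__ = ["GeneratorConfig", "generate_survey", "inject_missingness", "ROUND_PROFILES"]

#: marginal covariate levels by survey round (prevalences / means on the
#: natural scale); used as intercepts of the rank-gradient models
ROUND_PROFILES: dict[str, dict] = {
    "2000": {
        "male": 0.51,
        "in_school": 0.91,
        "father_edu": (0.60, 0.32, 0.08),
        "mother_edu": (0.69, 0.26, 0.05),
        "father_working": 0.93,
        "mother_working": 0.53,
        "father_cesd": 2.03,
        "mother_cesd": 2.56,
        "rural": 0.57,
        "javabali": 0.58,
        "electricity": 0.89,
        "improved_water": 0.51,
        "improved_sanitation": 0.44,
        "log_pce_mean": 11.93,
        "log_pce_sd": 0.70,
    },
    "2007": {
        "male": 0.52,
        "in_school": 0.95,
        "father_edu": (0.45, 0.44, 0.11),
        "mother_edu": (0.50, 0.42, 0.07),
        "father_working": 0.95,
        "mother_working": 0.49,
        "father_cesd": 3.29,
        "mother_cesd": 3.53,
        "rural": 0.49,
        "javabali": 0.59,
        "electricity": 0.96,
        "improved_water": 0.55,
        "improved_sanitation": 0.64,
        "log_pce_mean": 12.82,
        "log_pce_sd": 0.65,
    },
}

_DEFAULT_BETAS = {
    "log_pce": 0.30,
    "male": 0.25,
    "in_school": 0.45,
    "father_edu_hs": 0.05,
    "father_edu_uni": 0.30,
    "mother_edu_hs": 0.45,
    "mother_edu_uni": 0.40,
    "father_working": 0.10,
    "mother_working": 0.03,
    "father_cesd": -0.03,
    "mother_cesd": -0.03,
    "rural": -0.18,
    "javabali": 0.32,
    "electricity": 0.50,
    "improved_water": 0.0,
    "improved_sanitation": 0.35,
}

# log-odds (binary/ordinal) or log-scale (CES-D) change over the full rank
# span; positive -> concentrated among the better-off
_DEFAULT_GRADIENTS = {
    "male": 0.0,
    "in_school": 1.2,
    "father_edu": 2.8,
    "mother_edu": 3.0,
    "father_working": 0.4,
    "mother_working": 0.2,
    "father_cesd": -0.5,
    "mother_cesd": -0.5,
    "rural": -2.2,
    "javabali": 0.6,
    "electricity": 2.0,
    "improved_water": 1.2,
    "improved_sanitation": 2.4,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic survey; defaults emulate the 2000 round."""

    n_children: int = 5000
    seed: int = 0
    round_label: str = "2000"
    log_pce_mean: float | None = None  # None -> round profile value
    log_pce_sd: float | None = None
    true_betas: dict = field(default_factory=lambda: dict(_DEFAULT_BETAS))
    covariate_gradients: dict = field(default_factory=lambda: dict(_DEFAULT_GRADIENTS))
    noise_sd: float = 1.5
    weight_dispersion: float = 0.4
    missing_rate: float = 0.0
    age_range: tuple = (7, 14)
    score_intercept: float = 5.2
    age_slope: float = 0.40
    base_levels: dict | None = None  # overrides for the round profile

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ConfigError(f"n_children must be > 0, got {self.n_children}")
        profile = self._profile_defaults()
        if self.log_pce_mean is None:
            self.log_pce_mean = profile["log_pce_mean"]
        if self.log_pce_sd is None:
            self.log_pce_sd = profile["log_pce_sd"]
        if self.log_pce_sd <= 0:
            raise ConfigError(f"log_pce_sd must be > 0, got {self.log_pce_sd}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.weight_dispersion < 0:
            raise ConfigError(f"weight_dispersion must be >= 0, got {self.weight_dispersion}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        lo, hi = self.age_range
        if not (int(lo) == lo and int(hi) == hi and lo <= hi):
            raise ConfigError(f"age_range must be an ordered integer pair, got {self.age_range}")
        self.age_range = (int(lo), int(hi))
        unknown = set(self.true_betas) - set(CONTRIBUTORS)
        if unknown:
            raise ConfigError(f"true_betas has unknown contributors: {sorted(unknown)}")
        unknown = set(self.covariate_gradients) - set(_DEFAULT_GRADIENTS)
        if unknown:
            raise ConfigError(f"covariate_gradients has unknown covariates: {sorted(unknown)}")

    def _profile_defaults(self) -> dict:
        profile = dict(ROUND_PROFILES.get(self.round_label, ROUND_PROFILES["2000"]))
        if self.base_levels:
            profile.update(self.base_levels)
        return profile

    @property
    def levels(self) -> dict:
        return self._profile_defaults()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _gen_binary(rng, p0: float, grad: float, u: np.ndarray) -> np.ndarray:
    p = expit(logit(p0) + grad * (u - 0.5))
    return (rng.random(u.size) < p).astype(int)


def _gen_ordinal3(rng, probs, grad: float, u: np.ndarray) -> np.ndarray:
    """Ordered-logit draw of a 3-level category with marginals ``probs`` at
    zero gradient; higher latent -> higher category."""
    p0, p1, _ = probs
    c1, c2 = logit(p0), logit(p0 + p1)
    latent = grad * (u - 0.5) + rng.logistic(size=u.size)
    return np.digitize(latent, [c1, c2])  # 0, 1, 2


def generate_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one seeded survey round as a tidy child-level table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    lv = config.levels
    g = config.covariate_gradients

    log_pce = rng.normal(config.log_pce_mean, config.log_pce_sd, size=n)
    # fractional position of each child in the expenditure ordering
    u = np.empty(n)
    u[np.argsort(log_pce, kind="stable")] = (np.arange(n) + 0.5) / n

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)

    cols: dict[str, np.ndarray] = {}
    for c in ["male", "in_school", "father_working", "mother_working",
              "rural", "javabali", "electricity", "improved_water", "improved_sanitation"]:
        cols[c] = _gen_binary(rng, lv[c], g.get(c, 0.0), u)
    edu_codes = {}
    for c in ["father_edu", "mother_edu"]:
        edu_codes[c] = _gen_ordinal3(rng, lv[c], g.get(c, 0.0), u)
        cols[c] = np.array(EDU_LEVELS, dtype=object)[edu_codes[c]]
    for c in ["father_cesd", "mother_cesd"]:
        mean_c = lv[c] * np.exp(g.get(c, 0.0) * (u - 0.5))
        cols[c] = rng.gamma(shape=1.2, scale=mean_c / 1.2)

    betas = {k: config.true_betas.get(k, 0.0) for k in CONTRIBUTORS}
    latent = (
        config.score_intercept
        + config.age_slope * (age - config.age_range[0])
        + betas["log_pce"] * (log_pce - config.log_pce_mean)
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    for c in ["male", "in_school", "father_working", "mother_working", "rural",
              "javabali", "electricity", "improved_water", "improved_sanitation",
              "father_cesd", "mother_cesd"]:
        latent += betas[c] * cols[c]
    for parent in ["father", "mother"]:
        code = edu_codes[f"{parent}_edu"]
        latent += betas[f"{parent}_edu_hs"] * (code == 1)
        latent += betas[f"{parent}_edu_uni"] * (code == 2)
    raw_score = np.clip(np.rint(latent), 0, 12).astype(int)

    if config.weight_dispersion == 0:
        weight = np.ones(n)
    else:
        shape = 1.0 / config.weight_dispersion**2
        weight = rng.gamma(shape=shape, scale=1.0 / shape, size=n)

    table = pd.DataFrame(
        {
            "raw_score": raw_score,
            "age": age,
            "male": cols["male"],
            "in_school": cols["in_school"],
            "father_edu": cols["father_edu"],
            "mother_edu": cols["mother_edu"],
            "father_working": cols["father_working"],
            "mother_working": cols["mother_working"],
            "father_cesd": cols["father_cesd"],
            "mother_cesd": cols["mother_cesd"],
            "rural": cols["rural"],
            "javabali": cols["javabali"],
            "electricity": cols["electricity"],
            "improved_water": cols["improved_water"],
            "improved_sanitation": cols["improved_sanitation"],
            "log_pce": log_pce,
            "weight": weight,
            "round": config.round_label,
        }
    )
    if config.missing_rate > 0:
        table = inject_missingness(table, config)
    return table


#: columns eligible for MAR masking (never the outcome, age, log PCE, weight)
MISSABLE_COLUMNS = [
    "male",
    "in_school",
    "father_edu",
    "mother_edu",
    "father_working",
    "mother_working",
    "father_cesd",
    "mother_cesd",
    "rural",
    "javabali",
    "electricity",
    "improved_water",
    "improved_sanitation",
]

# MAR log-odds slopes on standardized log PCE and age: poorer and younger
# children have more missing parental/household information
_MAR_PCE_SLOPE = -0.8
_MAR_AGE_SLOPE = -0.3


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """MAR-mask covariate cells; marginal rate calibrated to ``missing_rate``.

    The row-level missingness propensity depends only on observed log PCE and
    age.  The same propensity applies independently to each eligible column.
    Seeded by ``config.seed`` only, so repeated calls are identical.
    """
    if config.missing_rate == 0:
        return table.copy()
    rng = np.random.default_rng([config.seed, 104729])
    z_pce = (table["log_pce"] - table["log_pce"].mean()) / table["log_pce"].std(ddof=0)
    z_age = (table["age"] - table["age"].mean()) / max(table["age"].std(ddof=0), 1e-12)
    score = _MAR_PCE_SLOPE * z_pce.to_numpy() + _MAR_AGE_SLOPE * z_age.to_numpy()

    def mean_rate(alpha: float) -> float:
        return float(np.mean(expit(alpha + score))) - config.missing_rate

    alpha = brentq(mean_rate, -30.0, 30.0)
    p_row = expit(alpha + score)

    out = table.copy()
    for col in MISSABLE_COLUMNS:
        mask = rng.random(len(out)) < p_row
        if col in ("father_edu", "mother_edu"):
            vals = out[col].astype(object)
            vals[mask] = np.nan
            out[col] = vals
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out
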