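"""Moment recovery from (min, median, max, n) summaries.

When a score distribution is reported (or treated) only through its range and
median, the mean and standard deviation can be approximated by the Hozo
estimator, with the approximation rule switching on the sample size n:

mean:
    n <= 25 : (a + 2m + b) / 4
    n >  25 : m
standard deviation:
    n <= 15        : sqrt( [ (a - 2m + b)^2 / 4 + (b - a)^2 ] / 12 )
    15 < n <= 70   : (b - a) / 4
    n >  70        : (b - a) / 6

where a, m, b are the sample minimum, median and maximum.  The branch
thresholds are exposed as keyword arguments so alternative cut-offs can be
tested without touching call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError

MEAN_FORMULA_MAX_N = 25
SD_FORMULA_MAX_N = 15
SD_RANGE4_MAX_N = 70


@dataclass(frozen=True)
class HozoSummary:
    """Order-statistic summary of a sample: minimum, median, maximum, size."""

    a: float
    m: float
    b: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.a > self.b:
            raise ConfigError(f"minimum a={self.a} exceeds maximum b={self.b}")
        if not (self.a <= self.m <= self.b):
            raise ConfigError(f"median m={self.m} outside [a={self.a}, b={self.b}]")


def hozo_mean(summary: HozoSummary, *, formula_max_n: int = MEAN_FORMULA_MAX_N) -> float:
    """Estimated mean from a (min, median, max, n) summary."""
    if summary.n <= formula_max_n:
        return (summary.a + 2.0 * summary.m + summary.b) / 4.0
    return float(summary.m)


def hozo_sd(
    summary: HozoSummary,
    *,
    formula_max_n: int = SD_FORMULA_MAX_N,
    range4_max_n: int = SD_RANGE4_MAX_N,
) -> float:
    """Estimated standard deviation from a (min, median, max, n) summary.

    Returns 0 for a degenerate summary with a == b.
    """
    a, m, b, n = summary.a, summary.m, summary.b, summary.n
    if b == a:
        return 0.0
    if n <= formula_max_n:
        return math.sqrt(((a - 2.0 * m + b) ** 2 / 4.0 + (b - a) ** 2) / 12.0)
    if n <= range4_max_n:
        return (b - a) / 4.0
    return (b - a) / 6.0
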