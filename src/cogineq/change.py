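"""Oaxaca-type decomposition of the change in the concentration index
between two survey rounds.

With eta_kt the elasticity and C_kt the contributor concentration index at
time t, the change C_t - C_{t-1} splits per contributor into a
change-in-inequality term and a change-in-elasticity term.  The default
weighting uses the current-period elasticity on the inequality change and
the base-period index on the elasticity change,

    d_inequality_k = eta_kt (C_kt - C_k,t-1)
    d_elasticity_k = C_k,t-1 (eta_kt - eta_k,t-1)

which (like the mirrored and symmetric average-weight variants, selectable
via ``variant``) sums with the residual change exactly to the difference of
the two total indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import DecompositionResult
from .errors import ConfigError, SchemaError

__all__ = ["ChangeDecomposition", "oaxaca_change", "format_table4"]

VARIANTS = ("current_elasticity", "base_elasticity", "average")


@dataclass
class ChangeDecomposition:
    """Per-contributor terms of the between-round inequality change.

    ``table`` is indexed by contributor with columns d_inequality,
    d_elasticity, total and percent_of_change (percent of the total change,
    residual included; the percent column sums to 100).
    """

    table: pd.DataFrame
    residual_change: float
    total_change: float
    rci_before: float
    rci_after: float
    variant: str = "current_elasticity"

    def additivity_gap(self) -> float:
        return abs(self.table["total"].sum() + self.residual_change - self.total_change)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "rci_before": self.rci_before,
            "rci_after": self.rci_after,
            "total_change": self.total_change,
            "residual_change": self.residual_change,
            "contributors": {
                k: {c: float(self.table.at[k, c]) for c in self.table.columns}
                for k in self.table.index
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def oaxaca_change(
    before: DecompositionResult,
    after: DecompositionResult,
    variant: str = "current_elasticity",
) -> ChangeDecomposition:
    """Decompose the change in the RCI between two fitted rounds."""
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    k_before, k_after = set(before.contributors), set(after.contributors)
    if k_before != k_after:
        raise SchemaError(
            "contributor sets differ between rounds: "
            f"only-before={sorted(k_before - k_after)}, only-after={sorted(k_after - k_before)}"
        )
    keys = before.contributors  # preserve base-round ordering
    eta0 = before.table["elasticity"]
    eta1 = after.table["elasticity"]
    c0 = before.table["ck"]
    c1 = after.table["ck"]
    if variant == "current_elasticity":
        d_ineq = eta1[keys] * (c1[keys] - c0[keys])
        d_elas = c0[keys] * (eta1[keys] - eta0[keys])
    elif variant == "base_elasticity":
        d_ineq = eta0[keys] * (c1[keys] - c0[keys])
        d_elas = c1[keys] * (eta1[keys] - eta0[keys])
    else:  # symmetric average weights
        d_ineq = 0.5 * (eta0[keys] + eta1[keys]) * (c1[keys] - c0[keys])
        d_elas = 0.5 * (c0[keys] + c1[keys]) * (eta1[keys] - eta0[keys])
    total = d_ineq + d_elas
    total_change = after.total_rci - before.total_rci
    residual_change = after.residual_contribution - before.residual_contribution
    table = pd.DataFrame(
        {
            "d_inequality": d_ineq,
            "d_elasticity": d_elas,
            "total": total,
            "percent_of_change": (
                total / total_change * 100.0 if total_change != 0 else np.nan
            ),
        },
        index=pd.Index(keys, name="contributor"),
    )
    return ChangeDecomposition(
        table=table,
        residual_change=float(residual_change),
        total_change=float(total_change),
        rci_before=before.total_rci,
        rci_after=after.total_rci,
        variant=variant,
    )


def format_table4(change: ChangeDecomposition) -> pd.DataFrame:
    """Report table sorted by descending percent of change, residual row
    included, with a bottom Total row equal to the column sums.

    Terms are printed at 2 decimals and percents as signed integers; the
    Total row is computed from the unrounded terms so it reproduces the
    overall change rather than the sum of rounded entries.
    """
    tab = change.table.copy()
    residual_pct = (
        change.residual_change / change.total_change * 100.0
        if change.total_change != 0
        else np.nan
    )
    tab.loc["residual"] = {
        "d_inequality": np.nan,
        "d_elasticity": np.nan,
        "total": change.residual_change,
        "percent_of_change": residual_pct,
    }
    tab = tab.sort_values("percent_of_change", ascending=False)
    out = pd.DataFrame(
        {
            "change_in_inequality": tab["d_inequality"].round(2),
            "change_in_elasticity": tab["d_elasticity"].round(2),
            "total": tab["total"].round(2),
            "percent": tab["percent_of_change"].round(0),
        },
        index=tab.index,
    )
    out.loc["Total"] = {
        "change_in_inequality": round(float(change.table["d_inequality"].sum()), 2),
        "change_in_elasticity": round(float(change.table["d_elasticity"].sum()), 2),
        "total": round(change.total_change, 2),
        "percent": 100.0,
    }
    return out
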