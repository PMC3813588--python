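"""Shared variable schema: survey columns and the regression design matrix.

Parental education is a three-level category (none/primary, high school,
university) and enters the outcome regression as two indicator columns per
parent with none/primary as the reference level, mirroring how the analysis
tables list "attended high school" / "attended university" rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

EDU_LEVELS = ["none_primary", "high_school", "university"]

BINARY_COLUMNS = [
    "male",
    "in_school",
    "father_working",
    "mother_working",
    "rural",
    "javabali",
    "electricity",
    "improved_water",
    "improved_sanitation",
]
CATEGORICAL_COLUMNS = ["father_edu", "mother_edu"]
CONTINUOUS_COLUMNS = ["father_cesd", "mother_cesd", "log_pce"]

#: survey columns that enter the outcome model (pre-dummy-expansion)
MODEL_COLUMNS = [
    "log_pce",
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

#: contributor names after expanding education into reference-coded dummies
CONTRIBUTORS = [
    "log_pce",
    "male",
    "in_school",
    "father_edu_hs",
    "father_edu_uni",
    "mother_edu_hs",
    "mother_edu_uni",
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

SURVEY_COLUMNS = (
    ["raw_score", "age"]
    + BINARY_COLUMNS[:2]  # male, in_school
    + CATEGORICAL_COLUMNS
    + ["father_working", "mother_working", "father_cesd", "mother_cesd"]
    + ["rural", "javabali", "electricity", "improved_water", "improved_sanitation"]
    + ["log_pce", "weight", "round"]
)


def build_design(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Expand survey columns into the numeric contributor design matrix.

    Education categories become 0/1 indicator columns ``*_edu_hs`` and
    ``*_edu_uni`` (reference: none/primary).  Missing cells propagate to NaN
    in every derived column.  No intercept column is added.
    """
    if columns is None:
        columns = MODEL_COLUMNS
    missing_cols = [c for c in columns if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"columns not present in table: {missing_cols}")
    out = {}
    for col in columns:
        s = table[col]
        if col in CATEGORICAL_COLUMNS:
            vals = s.astype(object)
            bad = set(vals.dropna().unique()) - set(EDU_LEVELS)
            if bad:
                raise SchemaError(f"{col} has undeclared levels: {sorted(bad)}")
            for suffix, level in (("hs", "high_school"), ("uni", "university")):
                dummy = (vals == level).astype(float)
                dummy[vals.isna()] = np.nan
                out[f"{col.split('_')[0]}_edu_{suffix}"] = dummy
        else:
            out[col] = pd.to_numeric(s, errors="coerce").astype(float)
    return pd.DataFrame(out, index=table.index)
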