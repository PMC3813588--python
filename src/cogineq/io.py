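"""CSV/JSON readers and writers.

CSV dialect: comma-separated, UTF-8, header row required, empty field =
missing.  JSON carries machine-readable results at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .concentration import RankedSample, concentration_curve
from .errors import SchemaError
from .model import CATEGORICAL_COLUMNS

__all__ = [
    "read_survey_csv",
    "write_survey_csv",
    "write_json",
    "read_json",
    "write_curve_csv",
]


def read_survey_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a child-level survey table; empty fields become missing."""
    table = pd.read_csv(path, na_values=[""], keep_default_na=True)
    if required:
        absent = [c for c in required if c not in table.columns]
        if absent:
            raise SchemaError(f"{path}: missing required columns {absent}")
    for c in CATEGORICAL_COLUMNS:
        if c in table.columns:
            table[c] = table[c].astype(object)
    if "round" in table.columns:
        table["round"] = table["round"].astype(str)
    return table


def write_survey_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write one child per line; missing cells as empty fields."""
    table.to_csv(path, index=False, na_rep="")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_curve_csv(sample: RankedSample, path: str | Path) -> None:
    """Export concentration-curve points as (population share, outcome share)."""
    pts = concentration_curve(sample)
    pd.DataFrame(pts, columns=["cum_population_share", "cum_outcome_share"]).to_csv(
        path, index=False
    )
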