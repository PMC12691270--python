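"""Reading and writing the cohort-table delimited-text format.

Comma-separated, header row, UTF-8; a missing cell is the empty string.
Column order is fixed (``id,siri,kps,bmi,smoking,time,event``); external
cohorts with different headers can be adapted with ``column_map``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import COHORT_COLUMNS, validate_cohort

__all__ = ["read_cohort", "write_cohort"]

_NUMERIC = ["siri", "kps", "bmi", "time", "event"]


def read_cohort(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    require_outcomes: bool = True,
) -> pd.DataFrame:
    """Read a cohort table; ``column_map`` maps external names to canonical ones."""
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True, na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    df = df[[c for c in COHORT_COLUMNS if c in df.columns] + extra]
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    validate_cohort(df, require_outcomes=require_outcomes)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, na_rep="", encoding="utf-8")
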