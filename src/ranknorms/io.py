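"""Survey CSV reading/writing and schema validation.

One row per respondent:

    id, brac_ug_per_100ml, gender {M,F}, location {1..n}, survey_after_23h
    {0,1}, session_duration_h, fast_score, age_years, judge_drunk,
    judge_extreme, judge_health15y, judge_cirrhosis15y

Empty string = missing; header required; UTF-8; decimal point.  Writing
then reading a table reproduces it exactly (floats round-trip through
their repr).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RATING_COLUMNS

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = (
    "id",
    "brac_ug_per_100ml",
    "gender",
    "location",
    "survey_after_23h",
    "session_duration_h",
    "fast_score",
    "age_years",
    *RATING_COLUMNS,
)

_FLOAT_COLUMNS = ("brac_ug_per_100ml", "session_duration_h", "age_years", *RATING_COLUMNS)
_INT_LIKE_COLUMNS = ("location", "survey_after_23h", "fast_score")


class SchemaError(ValueError):
    """The survey CSV violates the schema; carries per-row diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__(f"survey CSV schema violations:\n  {preview}{more}")


def write_survey_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a respondent table in the survey CSV dialect.

    Only schema columns are written (derived rank columns are dropped);
    missing values become empty strings.
    """
    path = Path(path)
    missing = [c for c in SURVEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError([f"table lacks required columns: {missing}"])
    out = table[list(SURVEY_COLUMNS)]
    out.to_csv(path, index=False, na_rep="")
    return path


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV; raises :class:`SchemaError` with
    per-row diagnostics on violation."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"id": str, "gender": str})
    problems: list[str] = []

    missing = [c for c in SURVEY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError([f"missing required columns: {missing}"])

    df = raw[list(SURVEY_COLUMNS)].copy()
    for col in (*_FLOAT_COLUMNS, *_INT_LIKE_COLUMNS):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = raw[col].notna() & df[col].isna()
        for i in np.flatnonzero(bad.to_numpy()):
            problems.append(f"row {i}: {col}={raw[col].iloc[i]!r} is not numeric")

    for i, g in enumerate(df["gender"]):
        if pd.notna(g) and g not in ("M", "F"):
            problems.append(f"row {i}: gender={g!r} not in {{M, F}}")
    neg = df["brac_ug_per_100ml"] < 0
    for i in np.flatnonzero(neg.to_numpy()):
        problems.append(f"row {i}: brac_ug_per_100ml={df['brac_ug_per_100ml'].iloc[i]} < 0")
    bad_flag = df["survey_after_23h"].notna() & ~df["survey_after_23h"].isin([0, 1])
    for i in np.flatnonzero(bad_flag.to_numpy()):
        problems.append(f"row {i}: survey_after_23h={df['survey_after_23h'].iloc[i]} not in {{0,1}}")
    # ratings are bounded to [1, 10] only when recorded on the discrete
    # instrument scale; continuous (model-generated) ratings may exceed it,
    # so out-of-range values are surfaced as warnings, not schema errors
    for col in RATING_COLUMNS:
        n_out = int((df[col].notna() & ((df[col] < 1) | (df[col] > 10))).sum())
        if n_out:
            logger.warning("%s: %d ratings outside the 1-10 instrument range", col, n_out)
    if df["id"].isna().any():
        for i in np.flatnonzero(df["id"].isna().to_numpy()):
            problems.append(f"row {i}: missing id")

    if problems:
        raise SchemaError(problems)

    # integer-like columns stay float if they carry missing values
    for col in ("location", "survey_after_23h", "fast_score"):
        if not df[col].isna().any():
            df[col] = df[col].astype(int)
    logger.info("read %d respondents from %s", len(df), path)
    return df
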