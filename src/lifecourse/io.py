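"""Cohort table schema, validation, and CSV round-trip.

One rectangular per-subject schema is shared by synthetic and real cohorts so
the pipeline runs unchanged on either. Adversity indicators are binary, the
cumulative scores are their within-period sums (0-3), and every subject
carries a positive survey sampling weight.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

BASELINE_CONFOUNDERS = ["sex", "age", "parental_education", "nativity"]
INTERMEDIATE_CONFOUNDERS = ["own_education", "household_income"]
ADVERSITY_TYPES = ["substance", "deprivation", "abuse"]
CHILD_COLS = [f"child_{t}" for t in ADVERSITY_TYPES]
ADULT_COLS = [f"adult_{t}" for t in ADVERSITY_TYPES]
CELL_COLS = ["cell_b", "cell_nk", "cell_cd4t", "cell_cd8t", "cell_mono", "cell_neu"]

REQUIRED_COLS = (
    BASELINE_CONFOUNDERS
    + CHILD_COLS
    + ["child_score"]
    + INTERMEDIATE_CONFOUNDERS
    + ADULT_COLS
    + ["adult_score", "outcome", "sampling_weight"]
)
OPTIONAL_COLS = ["smoking"] + CELL_COLS

_BINARY_COLS = (
    ["sex", "parental_education", "nativity"]
    + CHILD_COLS
    + INTERMEDIATE_CONFOUNDERS
    + ADULT_COLS
)


class SchemaError(ValueError):
    """Cohort file does not conform to the documented schema."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the shared schema.

    Checks column presence, missingness (imputation is out of scope: a cohort
    with missing values is rejected with a cell report), binary coding of the
    adversity indicators, score consistency, weight positivity, and -- when
    cell-type proportions are present -- that they lie on the simplex.

    Returns the validated frame (unmodified) so calls can be chained.
    """
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort is missing required columns: {missing}")

    used = [c for c in REQUIRED_COLS + OPTIONAL_COLS if c in df.columns]
    na = df[used].isna()
    if na.any().any():
        cells = [
            (int(i), c) for c in used for i in df.index[na[c]][:5]
        ]
        raise SchemaError(
            f"cohort contains missing values (imputation is out of scope); "
            f"first offending (row, column) cells: {cells[:10]}"
        )

    for c in _BINARY_COLS:
        vals = df[c].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"column {c!r} must be binary 0/1; first offending cell at row "
                f"{row} has value {df[c].iloc[int(np.flatnonzero(bad)[0])]!r}"
            )

    for period, cols in (("child", CHILD_COLS), ("adult", ADULT_COLS)):
        score = df[f"{period}_score"].to_numpy()
        expected = df[cols].to_numpy().sum(axis=1)
        if not np.array_equal(score, expected):
            row = int(np.flatnonzero(score != expected)[0])
            raise SchemaError(
                f"{period}_score must equal the sum of {cols}; "
                f"mismatch first at row {df.index[row]}"
            )
        if score.min() < 0 or score.max() > 3:
            raise SchemaError(f"{period}_score out of range 0-3")

    if (df["sampling_weight"].to_numpy() <= 0).any():
        raise SchemaError("sampling_weight must be strictly positive")

    if "smoking" in df.columns:
        if not np.isin(df["smoking"].to_numpy(), (0, 1, 2)).all():
            raise SchemaError("smoking must be coded 0=never, 1=former, 2=current")

    if all(c in df.columns for c in CELL_COLS):
        cells = df[CELL_COLS].to_numpy(float)
        if (cells < 0).any() or np.abs(cells.sum(axis=1) - 1.0).max() > 1e-6:
            raise SchemaError("cell-type proportions must be nonnegative and sum to 1")

    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort table to CSV (full float precision)."""
    validate_cohort(df)
    df.to_csv(path, index=False, float_format="%.17g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
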