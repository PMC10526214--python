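"""Cohort table schema, validation and CSV round-tripping.

A cohort table is a pandas DataFrame with one row per participant and a
fixed column set: six quantitative somatosensory scores (three modalities
x two hands), two categorical demographics, and an optional integer
``true_component`` carried only by synthetic cohorts.

Score conventions (instrument units):

==============  =========================================  ======  ==============
column          instrument                                 range   direction
==============  =========================================  ======  ==============
tdt_*           Tactile Discrimination Test, % max area    0-100   higher better
wpst_*          Wrist Position Sense Test, mean abs error  0-40    higher worse
ftort_*         functional Tactile Object Recognition,     0-42    higher better
                summed ordinal score (integer)
==============  =========================================  ======  ==============

``*_contra`` is the contralesional (typically more affected) hand,
``*_ipsi`` the ipsilesional hand.  Any score may be missing (NaN).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

#: Score columns in canonical order: hands-major, modality-minor.
SCORE_COLUMNS = (
    "tdt_contra",
    "wpst_contra",
    "ftort_contra",
    "tdt_ipsi",
    "wpst_ipsi",
    "ftort_ipsi",
)

#: Closed instrument bounds per score column.
SCORE_BOUNDS = {
    "tdt_contra": (0.0, 100.0),
    "wpst_contra": (0.0, 40.0),
    "ftort_contra": (0.0, 42.0),
    "tdt_ipsi": (0.0, 100.0),
    "wpst_ipsi": (0.0, 40.0),
    "ftort_ipsi": (0.0, 42.0),
}

#: Columns that hold integer-valued instrument sums.
INTEGER_SCORES = ("ftort_contra", "ftort_ipsi")

CATEGORICAL_COLUMNS = ("dominant_hand", "dominant_affected")
DOMINANT_HAND_LEVELS = ("R", "L", "unknown")
DOMINANT_AFFECTED_LEVELS = ("yes", "no", "unknown")

COHORT_COLUMNS = ("participant_id",) + SCORE_COLUMNS + CATEGORICAL_COLUMNS + ("true_component",)


class CohortValidationError(ValueError):
    """A cohort table violates its schema invariants."""


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Raise :class:`CohortValidationError` on any schema violation.

    Checks column presence, unique participant ids, instrument bounds on
    present scores, and integrality of present fTORT values.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort is missing columns: {missing_cols}")
    ids = cohort["participant_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5].tolist()
        raise CohortValidationError(f"duplicate participant ids: {dupes}")
    for col in SCORE_COLUMNS:
        vals = cohort[col].dropna()
        lo, hi = SCORE_BOUNDS[col]
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise CohortValidationError(
                f"{col} has {len(bad)} value(s) outside instrument bounds [{lo}, {hi}]"
            )
    for col in INTEGER_SCORES:
        vals = cohort[col].dropna()
        if len(vals) and not np.allclose(vals, np.round(vals)):
            raise CohortValidationError(f"{col} holds non-integer instrument sums")


def empty_cohort(n: int) -> pd.DataFrame:
    """Allocate an all-missing cohort table with ``n`` sequential ids."""
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            **{c: np.full(n, np.nan) for c in SCORE_COLUMNS},
            "dominant_hand": ["unknown"] * n,
            "dominant_affected": ["unknown"] * n,
            "true_component": np.full(n, np.nan),
        }
    )
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    """Write the canonical cohort CSV (empty cell = missing, LF endings)."""
    validate_cohort(cohort)
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    # keep fTORT and true_component as integers where present
    for col in INTEGER_SCORES + ("true_component",):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(round(v))))
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read and validate a cohort CSV produced by :func:`write_cohort_csv`."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "dominant_hand": str, "dominant_affected": str},
    )
    for col in CATEGORICAL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna("unknown")
    for col in SCORE_COLUMNS + ("true_component",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_cohort(df)
    return df
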