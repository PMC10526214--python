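"""Cohort -> feature-matrix preprocessing.

Mirrors the analysis pipeline's preparation steps: listwise deletion of
rows missing any analysed score, min-max normalization of scores to
[0, 1], and full one-hot encoding of the categorical demographics.
The assembled column order is deterministic: hands-major, modality-minor
for scores, categoricals last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import (
    DOMINANT_AFFECTED_LEVELS,
    DOMINANT_HAND_LEVELS,
    SCORE_BOUNDS,
)

HANDS = ("contralesional", "ipsilesional")
MODALITIES = ("TDT", "WPST", "fTORT")

_HAND_SUFFIX = {"contralesional": "contra", "ipsilesional": "ipsi"}
_MODALITY_PREFIX = {"TDT": "tdt", "WPST": "wpst", "fTORT": "ftort"}


def score_columns_for(hands, modalities) -> list[str]:
    """Cohort score columns for a (hands, modalities) selection, in
    canonical hands-major / modality-minor order."""
    cols = []
    for hand in HANDS:
        if hand not in hands:
            continue
        for mod in MODALITIES:
            if mod in modalities:
                cols.append(f"{_MODALITY_PREFIX[mod]}_{_HAND_SUFFIX[hand]}")
    return cols


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one clustering analysis.

    Parameters
    ----------
    hands, modalities
        Which limb(s) and somatosensory modalities enter the feature
        vector (non-empty subsets of ``HANDS`` / ``MODALITIES``).
    include_categoricals
        Append one-hot encoded hand dominance and dominant-affected flags.
    normalization_basis
        ``"observed"`` scales each score column by its observed min/max;
        ``"instrument_range"`` uses the fixed instrument bounds instead.
    spread_factor
        GSOM spread factor in (0, 1).
    k
        Cluster count, or an iterable of counts to search.
    """

    hands: tuple[str, ...] = ("contralesional",)
    modalities: tuple[str, ...] = ("TDT", "WPST")
    include_categoricals: bool = False
    normalization_basis: str = "observed"
    spread_factor: float = 0.9
    k: int | tuple[int, ...] = 3
    seed: int = 0

    def __post_init__(self):
        if not self.hands or any(h not in HANDS for h in self.hands):
            raise ValueError(f"hands must be a non-empty subset of {HANDS}")
        if not self.modalities or any(m not in MODALITIES for m in self.modalities):
            raise ValueError(f"modalities must be a non-empty subset of {MODALITIES}")
        if not 0.0 < self.spread_factor < 1.0:
            raise ValueError(f"spread_factor must lie in (0, 1), got {self.spread_factor}")
        if self.normalization_basis not in ("observed", "instrument_range"):
            raise ValueError(f"unknown normalization_basis {self.normalization_basis!r}")

    @property
    def score_columns(self) -> list[str]:
        return score_columns_for(self.hands, self.modalities)


@dataclass
class FeatureMatrix:
    """Normalized feature matrix with inverse-mapping metadata.

    ``data`` is a participant-indexed DataFrame with every value in
    [0, 1]; ``ranges`` retains each score column's (min, max) so original
    units can be recovered; one-hot columns have no range entry.
    """

    data: pd.DataFrame
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def inverse(self) -> pd.DataFrame:
        """Map score columns back to instrument units."""
        out = self.data.copy()
        for col, (lo, hi) in self.ranges.items():
            out[col] = out[col] * (hi - lo) + lo
        return out


def drop_incomplete(cohort: pd.DataFrame, required_features: list[str]) -> pd.DataFrame:
    """Listwise deletion: keep exactly the rows with all required scores
    present, preserving row order."""
    if not required_features:
        raise ValueError("required_features is empty")
    out = cohort.dropna(subset=list(required_features))
    if len(out) == 0:
        raise ValueError(
            "no rows are complete on the required features "
            f"{list(required_features)}; the analysis is infeasible"
        )
    return out


def minmax_normalize(
    matrix: pd.DataFrame, basis: str = "observed"
) -> FeatureMatrix:
    """Min-max scale every column to [0, 1].

    ``basis="observed"`` uses each column's observed extremes;
    ``basis="instrument_range"`` uses the fixed instrument bounds (the
    column must then be a known score column).
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing entries; apply drop_incomplete first")
    data = {}
    ranges = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if basis == "observed":
            lo, hi = float(x.min()), float(x.max())
            if hi - lo == 0:
                raise ValueError(
                    f"column {col!r} is constant; observed-basis normalization is undefined"
                )
        elif basis == "instrument_range":
            if col not in SCORE_BOUNDS:
                raise ValueError(f"column {col!r} has no instrument range")
            lo, hi = SCORE_BOUNDS[col]
        else:
            raise ValueError(f"unknown basis {basis!r}")
        data[col] = (x - lo) / (hi - lo)
        ranges[col] = (lo, hi)
    return FeatureMatrix(pd.DataFrame(data, index=matrix.index), ranges)


def one_hot_encode(column: pd.Series, levels: list[str]) -> pd.DataFrame:
    """Full one-hot encoding (one binary column per level).

    All levels get a column even if unobserved, so the encoding is stable
    across cohorts; a value outside ``levels`` is an error.
    """
    bad = column[~column.isin(levels)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"value {bad.iloc[0]!r} at row {row!r} is outside levels {list(levels)}"
        )
    cat = pd.Categorical(column, categories=list(levels))
    dummies = pd.get_dummies(cat, prefix=column.name, dtype=float)
    dummies.index = column.index
    return dummies


def assemble_features(cohort: pd.DataFrame, config: AnalysisConfig) -> FeatureMatrix:
    """Full preparation: select configured score columns, listwise-delete,
    normalize, optionally append one-hot categoricals."""
    featurizer = CohortFeaturizer(
        hands=config.hands,
        modalities=config.modalities,
        include_categoricals=config.include_categoricals,
        normalization_basis=config.normalization_basis,
    )
    return featurizer.fit_transform(cohort)


class CohortFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from a cohort table to a normalized feature matrix.

    scikit-learn-style: ``fit`` learns the normalization ranges from the
    (listwise-complete subset of the) cohort, ``transform`` applies them.
    Note that ``transform`` drops incomplete rows, so the output may have
    fewer rows than the input cohort.

    Parameters
    ----------
    hands, modalities, include_categoricals, normalization_basis
        See :class:`AnalysisConfig`.
    """

    def __init__(
        self,
        hands=("contralesional",),
        modalities=("TDT", "WPST"),
        include_categoricals=False,
        normalization_basis="observed",
    ):
        self.hands = hands
        self.modalities = modalities
        self.include_categoricals = include_categoricals
        self.normalization_basis = normalization_basis

    def _score_cols(self):
        cols = score_columns_for(self.hands, self.modalities)
        if not cols:
            raise ValueError("configuration selects no score columns")
        return cols

    def fit(self, cohort: pd.DataFrame, y=None):
        cols = self._score_cols()
        complete = drop_incomplete(cohort, cols)
        self.ranges_ = {}
        for col in cols:
            if self.normalization_basis == "observed":
                x = complete[col].to_numpy(dtype=float)
                lo, hi = float(x.min()), float(x.max())
                if hi - lo == 0:
                    raise ValueError(f"column {col!r} is constant under observed basis")
            elif self.normalization_basis == "instrument_range":
                lo, hi = SCORE_BOUNDS[col]
            else:
                raise ValueError(
                    f"unknown normalization_basis {self.normalization_basis!r}"
                )
            self.ranges_[col] = (lo, hi)
        # one-hot levels observed at fit, in canonical order ("unknown" is a
        # real level, never a dropped row)
        self.levels_ = {}
        if self.include_categoricals:
            for col, canon in (
                ("dominant_hand", DOMINANT_HAND_LEVELS),
                ("dominant_affected", DOMINANT_AFFECTED_LEVELS),
            ):
                observed = set(complete[col])
                self.levels_[col] = [l for l in canon if l in observed]
        self.feature_names_in_ = cols
        return self

    def transform(self, cohort: pd.DataFrame) -> FeatureMatrix:
        cols = self._score_cols()
        complete = drop_incomplete(cohort, cols).set_index("participant_id")
        data = {}
        for col in cols:
            lo, hi = self.ranges_[col]
            data[col] = (complete[col].to_numpy(dtype=float) - lo) / (hi - lo)
        frame = pd.DataFrame(data, index=complete.index)
        if self.include_categoricals:
            parts = [frame]
            for col in ("dominant_hand", "dominant_affected"):
                parts.append(one_hot_encode(complete[col], self.levels_[col]))
            frame = pd.concat(parts, axis=1)
        if ((frame.to_numpy() < -1e-12) | (frame.to_numpy() > 1 + 1e-12)).any():
            raise ValueError(
                "normalized values fall outside [0, 1]; scores exceed the fitted ranges"
            )
        return FeatureMatrix(frame.clip(0.0, 1.0), dict(self.ranges_))

    def fit_transform(self, cohort: pd.DataFrame, y=None) -> FeatureMatrix:
        return self.fit(cohort).transform(cohort)
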