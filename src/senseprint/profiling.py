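"""Severity-labelled signature profiles and recovery utilities.

Each somatosensory instrument has a published just-noticeable impairment
threshold (the 95th-percentile criterion of abnormality against healthy
controls) and an extreme-impairment threshold:

===========  =========  ===============  ========  ==============
instrument   direction  just noticeable  extreme   units
===========  =========  ===============  ========  ==============
TDT          higher =   73.1             33.3      % maximum area
             better
WPST         higher =   11.3             36        degrees error
             worse
fTORT        higher =   39.5             1.5       sum score
             better
===========  =========  ===============  ========  ==============

Scores on the unimpaired side of the just-noticeable threshold are
labelled ``none``; at or beyond the extreme threshold, ``extreme``.  The
interior impaired interval is split into three equal-width bands
``mild`` / ``moderate`` / ``severe`` ordered toward extreme — the
published profile labels use these words without numeric definitions, so
the simplest monotone banding is adopted and kept configurable.  A score
exactly on a band edge takes the more severe label, matching the
"less/greater than or equal to" convention of the thresholds themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort import SCORE_BOUNDS

SEVERITY_ORDER = ("none", "mild", "moderate", "severe", "extreme")


@dataclass(frozen=True)
class ModalityBands:
    """Severity banding for one instrument."""

    direction: str  # "higher_better" or "higher_worse"
    just_noticeable: float
    extreme: float
    bounds: tuple[float, float]

    def __post_init__(self):
        if self.direction not in ("higher_better", "higher_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "higher_better" and not self.extreme < self.just_noticeable:
            raise ValueError("higher_better requires extreme < just_noticeable")
        if self.direction == "higher_worse" and not self.just_noticeable < self.extreme:
            raise ValueError("higher_worse requires just_noticeable < extreme")

    def label(self, score: float) -> str:
        lo, hi = self.bounds
        if not lo <= score <= hi:
            raise ValueError(f"score {score} outside instrument range [{lo}, {hi}]")
        jn, ex = self.just_noticeable, self.extreme
        if self.direction == "higher_better":
            if score > jn:
                return "none"
            if score <= ex:
                return "extreme"
            # interior (ex, jn]: three equal bands, mild nearest jn;
            # band edges take the more severe label
            width = (jn - ex) / 3.0
            if score > jn - width:
                return "mild"
            if score > jn - 2.0 * width:
                return "moderate"
            return "severe"
        else:
            if score < jn:
                return "none"
            if score >= ex:
                return "extreme"
            width = (ex - jn) / 3.0
            if score < jn + width:
                return "mild"
            if score < jn + 2.0 * width:
                return "moderate"
            return "severe"


@dataclass(frozen=True)
class SeverityBands:
    """Per-modality severity banding (TDT, WPST, fTORT)."""

    tdt: ModalityBands
    wpst: ModalityBands
    ftort: ModalityBands

    def for_column(self, column: str) -> ModalityBands:
        prefix = column.split("_")[0]
        try:
            return getattr(self, prefix)
        except AttributeError:
            raise KeyError(f"no severity bands for column {column!r}") from None


DEFAULT_BANDS = SeverityBands(
    tdt=ModalityBands("higher_better", just_noticeable=73.1, extreme=33.3,
                      bounds=(0.0, 100.0)),
    wpst=ModalityBands("higher_worse", just_noticeable=11.3, extreme=36.0,
                       bounds=(0.0, 40.0)),
    ftort=ModalityBands("higher_better", just_noticeable=39.5, extreme=1.5,
                        bounds=(0.0, 42.0)),
)


def severity_label(score: float, bands: ModalityBands) -> str:
    """Severity label of a single instrument-unit score."""
    return bands.label(float(score))


_MODALITY_WORD = {"tdt": "touch", "wpst": "proprioception", "ftort": "object recognition"}
_HAND_WORD = {"contra": "contralesional", "ipsi": "ipsilesional"}


def _compose_label(severities: dict[str, str], high_variance: list[str]) -> str:
    """Human-readable cluster label from per-measure severities."""
    hands_present = {c.rsplit("_", 1)[1] for c in severities}
    parts = []
    for hand in ("contra", "ipsi"):
        cols = {c: s for c, s in severities.items() if c.endswith(hand)}
        if not cols:
            continue
        by_sev: dict[str, list[str]] = {}
        for col, sev in cols.items():
            by_sev.setdefault(sev, []).append(_MODALITY_WORD[col.split("_")[0]])
        chunks = []
        for sev in reversed(SEVERITY_ORDER):
            if sev in by_sev:
                mods = " and ".join(by_sev[sev])
                desc = "no impairment" if sev == "none" else f"{sev} impairment"
                chunks.append(f"{desc}—{mods}")
        text = "; ".join(chunks)
        parts.append(f"{text} ({_HAND_WORD[hand]})" if len(hands_present) > 1 else text)
    label = ". ".join(parts)
    if high_variance:
        label += " (high variance)"
    return label


def characterize_clusters(
    cohort: pd.DataFrame,
    participant_labels: pd.Series,
    bands: SeverityBands = DEFAULT_BANDS,
    score_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Signature-profile report: one row per (cluster, measure).

    Columns: cluster, n, pct, measure, mean, sd, severity (of the cluster
    mean), label (per-cluster composed text).  Means and SDs are in
    instrument units; SD is the sample SD (ddof=1).
    """
    sub = cohort.set_index("participant_id").loc[participant_labels.index]
    if score_columns is None:
        score_columns = [c for c in SCORE_BOUNDS if sub[c].notna().all()]
        if not score_columns:
            raise ValueError("no completely observed score columns to report")
    n_total = len(sub)
    clusters = sorted(pd.unique(participant_labels))
    pooled_sd = {c: sub[c].std(ddof=1) for c in score_columns}
    rows = []
    for cl in clusters:
        members = sub[participant_labels == cl]
        if len(members) == 0:
            raise ValueError(f"cluster {cl} is empty")
        severities = {}
        high_var = []
        for col in score_columns:
            severities[col] = bands.for_column(col).label(members[col].mean())
            sd = members[col].std(ddof=1)
            if np.isfinite(sd) and pooled_sd[col] > 0 and sd > 1.25 * pooled_sd[col]:
                high_var.append(col)
        label = _compose_label(severities, high_var)
        for col in score_columns:
            rows.append(
                dict(
                    cluster=cl,
                    n=len(members),
                    pct=100.0 * len(members) / n_total,
                    measure=col,
                    mean=float(members[col].mean()),
                    sd=float(members[col].std(ddof=1)),
                    severity=severities[col],
                    label=label,
                )
            )
    return pd.DataFrame(rows)


def categorical_composition(
    cohort: pd.DataFrame, participant_labels: pd.Series, variable: str
) -> pd.DataFrame:
    """Counts and within-cluster percentages of a categorical variable.

    Unknowns are reported as their own level, never dropped.
    """
    if variable not in cohort.columns:
        raise KeyError(f"unknown variable {variable!r}")
    sub = cohort.set_index("participant_id").loc[participant_labels.index]
    rows = []
    for cl in sorted(pd.unique(participant_labels)):
        members = sub[participant_labels == cl]
        counts = members[variable].value_counts()
        for level, count in counts.items():
            rows.append(
                dict(
                    cluster=cl,
                    level=level,
                    count=int(count),
                    pct=100.0 * count / len(members),
                )
            )
    return pd.DataFrame(rows)


def cross_cluster_table(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Contingency matrix of two labelings of the same participants.

    Rows are B profiles, columns A profiles; cell (i, j) counts
    participants in B-profile i and A-profile j, so row sums equal B
    cluster sizes and column sums equal A cluster sizes.
    """
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings cover different participant sets")
    labels_a = labels_a.loc[labels_b.index]
    table = pd.crosstab(labels_b, labels_a)
    table.index.name = "B_profile"
    table.columns.name = "A_profile"
    return table


def match_clusters(
    estimated_centroids: np.ndarray, reference_centroids: np.ndarray
) -> np.ndarray:
    """Best bijection estimated -> reference by exhaustive permutation.

    Returns ``perm`` with ``perm[i]`` the reference index assigned to
    estimated cluster ``i``, minimizing the summed Euclidean centroid
    distance.  Exhaustive over k! permutations, k <= 6.
    """
    est = np.asarray(estimated_centroids, dtype=float)
    ref = np.asarray(reference_centroids, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"centroid sets differ in shape: {est.shape} vs {ref.shape}")
    k = len(est)
    if k > 6:
        raise ValueError("exhaustive matching supports k <= 6")
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(k)):
        cost = sum(np.linalg.norm(est[i] - ref[perm[i]]) for i in range(k))
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return np.array(best_perm)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index between two labelings (1 = identical)."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            raise ValueError("labelings cover different participant sets")
        b = b.loc[a.index]
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
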