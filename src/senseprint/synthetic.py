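"""Synthetic stroke-cohort generator.

The raw pooled cohort behind the published signature profiles is not
publicly available, so analyses are exercised on synthetic cohorts drawn
from truncated-Gaussian mixtures whose component proportions, per-feature
means and SDs are transcribed from the printed per-profile summary tables
(see :mod:`senseprint.presets`).  Each mixture component plays the role of
one impairment profile; the generator records the drawn component so that
cluster-recovery experiments can score against ground truth.

Within a component, features are drawn independently (diagonal
covariance): only marginal per-cluster means and SDs are published, so no
within-profile correlation structure can be emulated.  Truncation to the
instrument bounds is exact (rejection sampling); fTORT scores are rounded
to the nearest integer after truncation because the instrument is a sum
of ordinal item scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CATEGORICAL_COLUMNS,
    INTEGER_SCORES,
    SCORE_BOUNDS,
    SCORE_COLUMNS,
    empty_cohort,
    validate_cohort,
)


class MixtureSpecError(ValueError):
    """A mixture specification violates its invariants."""


@dataclass(frozen=True)
class MixtureComponent:
    """One impairment-profile component of a generating mixture."""

    proportion: float
    means: dict[str, float]
    sds: dict[str, float]


@dataclass(frozen=True)
class ProfileMixtureSpec:
    """Generating parameters for a synthetic cohort.

    Parameters
    ----------
    components
        Mixture components; proportions must sum to 1 within 1e-9.
    features
        Ordered score-column names (subset of :data:`~senseprint.cohort.SCORE_COLUMNS`);
        every component must provide a mean and SD for each.
    bounds
        Per-feature closed truncation interval in instrument units.
    """

    components: tuple[MixtureComponent, ...]
    features: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.components:
            raise MixtureSpecError("mixture needs at least one component")
        if not self.features:
            raise MixtureSpecError("mixture needs at least one feature")
        bounds = dict(self.bounds) or {f: SCORE_BOUNDS[f] for f in self.features}
        for f in self.features:
            bounds.setdefault(f, SCORE_BOUNDS[f])
            lo, hi = bounds[f]
            if not lo < hi:
                raise MixtureSpecError(f"feature {f!r}: bounds [{lo}, {hi}] have no width")
        object.__setattr__(self, "bounds", bounds)
        total = 0.0
        for i, comp in enumerate(self.components):
            if comp.proportion < 0:
                raise MixtureSpecError(f"component {i}: negative proportion {comp.proportion}")
            total += comp.proportion
            for f in self.features:
                if f not in comp.means or f not in comp.sds:
                    raise MixtureSpecError(f"component {i}: missing feature {f!r}")
                if not comp.sds[f] > 0:
                    raise MixtureSpecError(
                        f"component {i}: sd for {f!r} must be > 0, got {comp.sds[f]}"
                    )
        if abs(total - 1.0) > 1e-9:
            raise MixtureSpecError(f"component proportions sum to {total}, expected 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c.proportion for c in self.components])

    def component_means(self) -> np.ndarray:
        """(k, n_features) matrix of generating means in instrument units."""
        return np.array([[c.means[f] for f in self.features] for c in self.components])

    def component_sds(self) -> np.ndarray:
        """(k, n_features) matrix of generating SDs in instrument units."""
        return np.array([[c.sds[f] for f in self.features] for c in self.components])


@dataclass(frozen=True)
class DemographicRates:
    """Bernoulli rates for the categorical demographics.

    ``p_dominant_affected`` may be a single global fraction or a
    per-component sequence (one rate per mixture component, applied via
    the cohort's ``true_component`` labels).
    """

    p_right_dominant: float = 178 / 207
    p_unknown_dominance: float = 4 / 207
    p_dominant_affected: float | tuple[float, ...] = 101 / 207

    def __post_init__(self):
        rates = [self.p_right_dominant, self.p_unknown_dominance]
        pda = self.p_dominant_affected
        rates += list(pda) if isinstance(pda, (tuple, list)) else [pda]
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise MixtureSpecError(f"demographic rate {r} outside [0, 1]")
        if self.p_right_dominant + self.p_unknown_dominance > 1.0 + 1e-12:
            raise MixtureSpecError("p_right_dominant + p_unknown_dominance exceeds 1")


def mixture_from_table(
    component_params: list[dict],
    bounds: dict[str, tuple[float, float]] | None = None,
    features: list[str] | None = None,
) -> ProfileMixtureSpec:
    """Build a validated :class:`ProfileMixtureSpec` from per-profile rows.

    Each entry of ``component_params`` is a mapping with keys
    ``proportion``, ``means`` and ``sds``, the latter two mapping feature
    name -> instrument-unit value, exactly as printed in a profile table.
    Feature order defaults to the order of the first component's means.
    """
    if not component_params:
        raise MixtureSpecError("component_params is empty")
    feats = tuple(features) if features is not None else tuple(component_params[0]["means"])
    comps = tuple(
        MixtureComponent(
            proportion=float(p["proportion"]),
            means={k: float(v) for k, v in p["means"].items()},
            sds={k: float(v) for k, v in p["sds"].items()},
        )
        for p in component_params
    )
    return ProfileMixtureSpec(components=comps, features=feats, bounds=dict(bounds or {}))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Exact truncated-normal draws by rejection from N(mean, sd)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(spec: ProfileMixtureSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` participants from a profile mixture.

    Component membership is multinomial on the spec proportions; each
    feature is an independent truncated normal within the component.
    Identical ``(spec, n, seed)`` reproduces the identical table;
    ``true_component`` records the drawn component (0-based).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cohort = empty_cohort(n)
    comp_idx = rng.choice(len(spec.components), size=n, p=spec.proportions)
    cohort["true_component"] = comp_idx.astype(float)
    for ci, comp in enumerate(spec.components):
        mask = comp_idx == ci
        m = int(mask.sum())
        if m == 0:
            continue
        for f in spec.features:
            lo, hi = spec.bounds[f]
            vals = _truncated_normal(rng, comp.means[f], comp.sds[f], lo, hi, m)
            if f in INTEGER_SCORES:
                vals = np.clip(np.round(vals), lo, hi)
            cohort.loc[mask, f] = vals
    validate_cohort(cohort)
    return cohort


def attach_demographics(
    cohort: pd.DataFrame, rates: DemographicRates, seed: int
) -> pd.DataFrame:
    """Draw categorical demographics onto a copy of ``cohort``.

    Hand dominance is drawn globally (R / L / unknown); the
    dominant-hand-affected flag is drawn globally or, when
    ``rates.p_dominant_affected`` is a per-component sequence, per the
    ``true_component`` of each row (emulating profiles whose composition
    differs, e.g. an all-dominant-affected profile).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    u = rng.random(n)
    p_r, p_unk = rates.p_right_dominant, rates.p_unknown_dominance
    out["dominant_hand"] = np.where(u < p_r, "R", np.where(u < p_r + p_unk, "unknown", "L"))
    pda = rates.p_dominant_affected
    if isinstance(pda, (tuple, list)):
        comp = out["true_component"]
        if comp.isna().any():
            raise ValueError("per-component rates require true_component labels")
        p_row = np.array([pda[int(c)] for c in comp])
    else:
        p_row = np.full(n, pda)
    out["dominant_affected"] = np.where(rng.random(n) < p_row, "yes", "no")
    return out


def inject_missingness(
    cohort: pd.DataFrame, rate_per_field: dict[str, float], seed: int
) -> pd.DataFrame:
    """Set targeted score fields missing completely at random.

    Each targeted field is independently blanked with its own rate;
    reproducible under ``seed``.
    """
    for col, rate in rate_per_field.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col!r} outside [0, 1]: {rate}")
        if col not in SCORE_COLUMNS and col not in CATEGORICAL_COLUMNS:
            raise ValueError(f"unknown field {col!r}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col in SCORE_COLUMNS:  # fixed iteration order keeps the stream stable
        if col in rate_per_field:
            mask = rng.random(len(out)) < rate_per_field[col]
            out.loc[mask, col] = np.nan
    for col in CATEGORICAL_COLUMNS:
        if col in rate_per_field:
            mask = rng.random(len(out)) < rate_per_field[col]
            out.loc[mask, col] = "unknown"
    return out
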