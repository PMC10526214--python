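import numpy as np
import pandas as pd
import pytest

from senseprint import get_preset
from senseprint.cohort import empty_cohort
from senseprint.recovery import recovery_experiment

RECOVERY_SEEDS = tuple(range(1, 21))


def make_cohort(scores: dict, dominant_hand=None, dominant_affected=None) -> pd.DataFrame:
    """Small cohort table from per-column score lists."""
    n = len(next(iter(scores.values())))
    cohort = empty_cohort(n)
    for col, vals in scores.items():
        cohort[col] = [np.nan if v is None else float(v) for v in vals]
    if dominant_hand is not None:
        cohort["dominant_hand"] = list(dominant_hand)
    if dominant_affected is not None:
        cohort["dominant_affected"] = list(dominant_affected)
    return cohort


@pytest.fixture(scope="session")
def recovery_3a():
    """Full-pipeline recovery on the two-modality contralesional mixture,
    20 seeds; shared across recovery and distinctiveness tests."""
    p = get_preset("table3a")
    return p, recovery_experiment(p["spec"], p["n"], p["k"], RECOVERY_SEEDS)


@pytest.fixture(scope="session")
def recovery_4a():
    """Full-pipeline recovery on the three-modality contralesional mixture."""
    p = get_preset("table4a")
    return p, recovery_experiment(p["spec"], p["n"], p["k"], RECOVERY_SEEDS)
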