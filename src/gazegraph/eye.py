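"""Eye-tracking fixation features and random-forest feature ranking.

Each subject watched seven stimulus tests (native/exotic faces, joint
attention, gaze following, social interaction); the per-test feature is the
total fixation duration on the test's area of interest, after discarding
fixations shorter than 60 ms (treated as unconscious gazing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "TEST_NAMES",
    "FixationRecord",
    "EyeFeatureSet",
    "MIN_FIXATION_MS",
    "total_fixation_duration",
    "extract_eye_features",
    "first_fixation_latency",
    "rank_features_random_forest",
]

#: The closed set of stimulus tests, in the fixed node order of the
#: feature graph's eye-tracking block.
TEST_NAMES = (
    "ExoticFace",
    "SocialInteraction",
    "JointAttention",
    "ModJoint1",
    "ModJoint2",
    "NativeFace1",
    "NativeFace2",
)

#: Fixations shorter than this are treated as unconscious gazing.
MIN_FIXATION_MS = 60.0


@dataclass(frozen=True)
class FixationRecord:
    """One fixation event: which test, which AOI, when and for how long."""

    test: str
    aoi: str
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.test not in TEST_NAMES:
            raise ValueError(f"unknown test {self.test!r}; expected one of {TEST_NAMES}")
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be >= 0")


@dataclass
class EyeFeatureSet:
    """Per-test total fixation durations (ms) for one subject."""

    durations_ms: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.durations_ms) != set(TEST_NAMES):
            raise ValueError("EyeFeatureSet must have exactly the 7 test entries")
        if any(v < 0 for v in self.durations_ms.values()):
            raise ValueError("fixation durations must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.durations_ms[t] for t in TEST_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {t: float(self.durations_ms[t]) for t in TEST_NAMES}


def total_fixation_duration(
    records: Iterable[FixationRecord], test: str, min_ms: float = MIN_FIXATION_MS
) -> float:
    """Sum of fixation durations for one test, dropping sub-threshold events."""
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; expected one of {TEST_NAMES}")
    if min_ms < 0:
        raise ValueError("min_ms must be >= 0")
    return float(
        sum(r.duration_ms for r in records if r.test == test and r.duration_ms >= min_ms)
    )


def extract_eye_features(
    records: Sequence[FixationRecord], min_ms: float = MIN_FIXATION_MS
) -> EyeFeatureSet:
    """The seven per-test total fixation durations of one subject.

    A test with no fixation records contributes 0 ms with a warning.
    """
    present = {r.test for r in records}
    missing = [t for t in TEST_NAMES if t not in present]
    if missing:
        warnings.warn(f"no fixation records for test(s) {missing}; using 0 ms", stacklevel=2)
    return EyeFeatureSet(
        durations_ms={t: total_fixation_duration(records, t, min_ms) for t in TEST_NAMES}
    )


def first_fixation_latency(
    records: Iterable[FixationRecord], test: str, min_ms: float = MIN_FIXATION_MS
) -> float:
    """Onset of the earliest valid fixation in a test (optional feature family).

    Disabled in the default 14-node graph, which has no slots for latency
    features; returns NaN when the test has no valid fixation.
    """
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; expected one of {TEST_NAMES}")
    onsets = [r.onset_ms for r in records if r.test == test and r.duration_ms >= min_ms]
    return float(min(onsets)) if onsets else float("nan")


def rank_features_random_forest(
    feature_table: pd.DataFrame,
    labels: Sequence[str],
    keep_k: int | None = None,
    seed: int = 0,
    n_estimators: int = 500,
) -> tuple[list[str], pd.Series]:
    """Rank features by random-forest mean impurity decrease.

    Parameters
    ----------
    feature_table : DataFrame, subjects x features
    labels : group label per subject (exactly two classes)
    keep_k : how many top features to retain; default keeps all of them, so
        by default the ranking is reported but nothing is filtered out
        (the 14-node graph uses all seven eye features).
    seed : makes tree construction deterministic.

    Returns
    -------
    (retained, importances) : the top-``keep_k`` feature names in descending
        importance order, and the full importance series.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to rank features")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    k = keep_k if keep_k is not None else feature_table.shape[1]
    if not 1 <= k <= feature_table.shape[1]:
        raise ValueError("keep_k out of range")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(feature_table.to_numpy(), labels)
    importances = pd.Series(rf.feature_importances_, index=feature_table.columns)
    order = importances.sort_values(ascending=False, kind="stable").index.tolist()
    return order[:k], importances
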