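"""Train/test splitting, classification metrics, per-feature t-tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "TTestResult",
    "train_test_split",
    "confusion_from_predictions",
    "classification_metrics",
    "two_sample_ttest",
    "feature_ttest_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is the clinical group."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class TTestResult:
    feature: str
    statistic: float
    p_value: float


def train_test_split(
    sample_ids: Sequence,
    groups: Sequence[str],
    subject_ids: Sequence | None = None,
    train_ratio: float = 0.8,
    seed: int = 0,
    unit: Literal["segment", "subject"] = "segment",
) -> tuple[list, list]:
    """Stratified 8:2 split of samples into train and test indices.

    In "segment" mode samples are split directly; in "subject" mode the
    split is made over subjects (stratified by group) and every sample of
    a subject lands on the same side — the safer protocol when segments of
    one subject are not independent.

    Returns (train_indices, test_indices) into the input sequences.
    """
    if not 0 < train_ratio < 1:
        raise ValueError("train_ratio must be in (0, 1)")
    groups = list(groups)
    idx = np.arange(len(sample_ids))
    if unit == "segment":
        tr, te = _sk_split(
            idx, train_size=train_ratio, stratify=groups, random_state=seed
        )
    else:
        if subject_ids is None:
            raise ValueError("subject mode needs subject_ids")
        subject_ids = list(subject_ids)
        subj_group = {}
        for s, g in zip(subject_ids, groups):
            if subj_group.setdefault(s, g) != g:
                raise ValueError(f"subject {s} has inconsistent group labels")
        subjects = sorted(subj_group)
        tr_subj, _ = _sk_split(
            subjects,
            train_size=train_ratio,
            stratify=[subj_group[s] for s in subjects],
            random_state=seed,
        )
        tr_set = set(tr_subj)
        tr = idx[[s in tr_set for s in subject_ids]]
        te = idx[[s not in tr_set for s in subject_ids]]
    for side, name in ((tr, "train"), (te, "test")):
        present = {groups[i] for i in side}
        if present != set(groups):
            raise ValueError(f"group(s) {set(groups) - present} absent from {name} side")
    return sorted(int(i) for i in tr), sorted(int(i) for i in te)


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], positive: str
) -> ConfusionMatrix:
    """Tally a binary confusion matrix with ``positive`` as the positive class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = sum(t == positive and p == positive for t, p in zip(y_true, y_pred))
    fp = sum(t != positive and p == positive for t, p in zip(y_true, y_pred))
    fn = sum(t == positive and p != positive for t, p in zip(y_true, y_pred))
    tn = sum(t != positive and p != positive for t, p in zip(y_true, y_pred))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    A zero denominator (no predicted or no actual positives) makes the
    affected metric 0, with a warning, rather than NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    feature: str = "",
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(feature=feature, statistic=float(res.statistic), p_value=float(res.pvalue))


def feature_ttest_table(
    table: pd.DataFrame,
    groups: Sequence[str],
    feature_columns: Sequence[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature group contrast table (statistic and p-value per feature).

    ``table`` holds one row per observation (typically one per subject,
    features averaged over segments first) and ``groups`` the matching
    group labels; the first label in sorted order is the "a" side.
    """
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    mask_a = np.asarray([g == labels[0] for g in groups])
    rows = []
    for col in feature_columns:
        res = two_sample_ttest(
            table.loc[mask_a, col], table.loc[~mask_a, col], feature=col, equal_var=equal_var
        )
        rows.append({"feature": col, "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows)
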