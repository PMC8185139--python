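"""End-to-end pipeline: features -> feature graph -> GCN -> metrics.

Orchestrates the whole method on a cohort: per-segment EEG features and
per-subject eye features are fused into 14-node sample graphs sharing one
covariance-thresholded adjacency, a two-weight-matrix GCN is trained on an
8:2 stratified split, and held-out graphs are scored.  Everything fitted
(feature standardization, the adjacency, the random-forest ranking, the
GCN) is fitted on the training fold only unless the flagged
``allow_leakage`` mode is switched on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .eeg import EEG_FEATURE_NAMES, EEGFeatureConfig, extract_eeg_features, segment_recording
from .eye import MIN_FIXATION_MS, TEST_NAMES, extract_eye_features, rank_features_random_forest
from .gcn import TrainConfig, gcn_forward, normalize_adjacency, predict_graphs, train_gcn
from .graph import (
    NODE_NAMES,
    FeatureGraph,
    batch_graphs,
    covariance_adjacency_from_matrix,
)
from .synthetic import SyntheticSubject

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "extract_cohort_features",
    "run_pipeline_from_features",
    "run_pipeline",
    "compare_modalities",
]

MODALITY_COLUMNS = {
    "eeg": list(EEG_FEATURE_NAMES),
    "eye": list(TEST_NAMES),
    "both": list(NODE_NAMES),
}


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with the documented defaults."""

    modality: Literal["both", "eeg", "eye"] = "both"
    tau: float = 0.3
    adjacency_mode: Literal["absolute", "signed"] = "absolute"
    train_ratio: float = 0.8
    split_unit: Literal["segment", "subject"] = "segment"
    window_s: float = 4.0
    overlap_s: float = 0.0
    min_fixation_ms: float = MIN_FIXATION_MS
    rf_keep_k: int | None = None  # None -> keep all ranked features
    eeg_features: EEGFeatureConfig = field(default_factory=EEGFeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    positive_class: str | None = None  # None -> "ASD" if present, else first sorted
    allow_leakage: bool = False  # fit adjacency/standardization on all samples (flagged)


@dataclass
class PipelineResult:
    metrics: ev.MetricsReport
    confusion: ev.ConfusionMatrix
    ttest_table: pd.DataFrame
    covariance: np.ndarray
    adjacency: np.ndarray
    node_names: list[str]
    loss_trace: np.ndarray
    rf_ranking: list[str]
    rf_importances: pd.Series
    n_train: int
    n_test: int
    predictions: pd.DataFrame


def extract_cohort_features(
    subjects: Sequence[SyntheticSubject],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-sample feature table for a cohort.

    Each EEG segment of each subject yields one row: sample_id, subject_id,
    group, the 7 EEG features of that segment, and the subject's 7 eye
    features (identical across the subject's rows).
    """
    cfg = config or PipelineConfig()
    rows = []
    for subj in subjects:
        eye = extract_eye_features(subj.fixations, cfg.min_fixation_ms).as_dict()
        segments = segment_recording(subj.eeg, cfg.window_s, cfg.overlap_s)
        for seg in segments:
            eeg = extract_eeg_features(seg, cfg.eeg_features).as_dict()
            rows.append(
                {
                    "sample_id": f"{subj.subject_id}_seg{seg.index:03d}",
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                }
                | eeg
                | eye
            )
    if not rows:
        raise ValueError("cohort produced no samples (recordings shorter than one window?)")
    return pd.DataFrame(rows)


def _resolve_positive(groups: Sequence[str], positive: str | None) -> str:
    labels = sorted(set(groups))
    if positive is not None:
        if positive not in labels:
            raise ValueError(f"positive class {positive!r} not among groups {labels}")
        return positive
    return "ASD" if "ASD" in labels else labels[0]


def run_pipeline_from_features(
    features: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Split, fit and score on a precomputed per-sample feature table.

    ``seed`` governs the split, the random-forest ranking and the GCN
    initialization, so a run is fully reproducible from (features, config,
    seed).
    """
    cfg = config or PipelineConfig()
    cols = MODALITY_COLUMNS[cfg.modality]
    groups = features["group"].tolist()
    if len(set(groups)) != 2:
        raise ValueError(f"expected 2 groups, got {sorted(set(groups))}")
    positive = _resolve_positive(groups, cfg.positive_class)

    tr_idx, te_idx = ev.train_test_split(
        features["sample_id"].tolist(),
        groups,
        subject_ids=features["subject_id"].tolist(),
        train_ratio=cfg.train_ratio,
        seed=seed,
        unit=cfg.split_unit,
    )
    fit_idx = list(range(len(features))) if cfg.allow_leakage else tr_idx
    if cfg.allow_leakage:
        warnings.warn("allow_leakage=True: graph and scaling fitted on all samples", stacklevel=2)

    x_all = features[cols].to_numpy(dtype=float)
    x_fit = x_all[fit_idx]

    # random-forest ranking of the eye features (reported; filters only if keep_k set)
    rf_ranking: list[str] = []
    rf_importances = pd.Series(dtype=float)
    if cfg.modality in ("eye", "both"):
        subj_table = (
            features.iloc[fit_idx]
            .groupby("subject_id")
            .agg({**{c: "mean" for c in TEST_NAMES}, "group": "first"})
        )
        rf_ranking, rf_importances = rank_features_random_forest(
            subj_table[list(TEST_NAMES)],
            subj_table["group"].tolist(),
            keep_k=cfg.rf_keep_k,
            seed=seed,
        )
        if cfg.rf_keep_k is not None and cfg.rf_keep_k < len(TEST_NAMES):
            dropped = set(TEST_NAMES) - set(rf_ranking)
            cols = [c for c in cols if c not in dropped]
            x_all = features[cols].to_numpy(dtype=float)
            x_fit = x_all[fit_idx]

    # shared adjacency and node standardization from the fit fold only
    cov, adjacency = covariance_adjacency_from_matrix(
        x_fit, cols, tau=cfg.tau, mode=cfg.adjacency_mode
    )
    mu = x_fit.mean(axis=0)
    sd = x_fit.std(axis=0, ddof=1)
    x_std = (x_all - mu) / sd

    def make_batch(idx: list[int], with_labels: bool):
        graphs = [
            FeatureGraph(
                node_names=tuple(cols),
                attributes=x_std[i],
                adjacency=adjacency,
                label=groups[i] if with_labels else None,
            )
            for i in idx
        ]
        return batch_graphs(graphs)

    train_batch = make_batch(tr_idx, with_labels=True)
    adj_train = normalize_adjacency(train_batch.adjacency)
    params, classes, trace = train_gcn(
        train_batch, adj_train, replace(cfg.train, seed=seed)
    )

    test_batch = make_batch(te_idx, with_labels=False)
    adj_test = normalize_adjacency(test_batch.adjacency)
    z = gcn_forward(test_batch.attributes, adj_test, params)
    y_pred = predict_graphs(z, test_batch.membership, classes)
    y_true = [groups[i] for i in te_idx]

    cm = ev.confusion_from_predictions(y_true, y_pred, positive=positive)
    metrics = ev.classification_metrics(cm)

    # Table-1-style subject-level contrast report over the whole cohort
    subj_means = features.groupby("subject_id").agg(
        {**{c: "mean" for c in MODALITY_COLUMNS[cfg.modality]}, "group": "first"}
    )
    ttests = ev.feature_ttest_table(
        subj_means, subj_means["group"].tolist(), MODALITY_COLUMNS[cfg.modality]
    )

    predictions = pd.DataFrame(
        {
            "sample_id": [features["sample_id"].iloc[i] for i in te_idx],
            "subject_id": [features["subject_id"].iloc[i] for i in te_idx],
            "true": y_true,
            "predicted": y_pred,
        }
    )
    return PipelineResult(
        metrics=metrics,
        confusion=cm,
        ttest_table=ttests,
        covariance=cov,
        adjacency=adjacency,
        node_names=list(cols),
        loss_trace=trace,
        rf_ranking=rf_ranking,
        rf_importances=rf_importances,
        n_train=len(tr_idx),
        n_test=len(te_idx),
        predictions=predictions,
    )


def run_pipeline(
    subjects: Sequence[SyntheticSubject],
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Full run from raw cohort to metrics, optionally writing artifacts.

    Artifacts written under ``outdir``: the per-sample feature table, the
    covariance and adjacency matrices (CSV with node-name headers), the
    per-feature t-test table, the training loss trace and a metrics JSON.
    """
    cfg = config or PipelineConfig()
    features = extract_cohort_features(subjects, cfg)
    result = run_pipeline_from_features(features, cfg, seed)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        pd.DataFrame(result.covariance, index=result.node_names, columns=result.node_names).to_csv(
            out / "covariance.csv"
        )
        pd.DataFrame(result.adjacency, index=result.node_names, columns=result.node_names).to_csv(
            out / "adjacency.csv"
        )
        result.ttest_table.to_csv(out / "ttests.csv", index=False)
        pd.DataFrame({"epoch": np.arange(len(result.loss_trace)), "loss": result.loss_trace}).to_csv(
            out / "loss_trace.csv", index=False
        )
        result.predictions.to_csv(out / "predictions.csv", index=False)
        (out / "metrics.json").write_text(
            json.dumps(
                result.metrics.as_dict()
                | {
                    "n_train": result.n_train,
                    "n_test": result.n_test,
                    "confusion": vars(result.confusion),
                    "seed": seed,
                },
                indent=2,
            )
        )
    return result


def compare_modalities(
    features: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> dict[str, ev.MetricsReport]:
    """EEG-only vs eye-only vs fused runs on the same split seed.

    The three rows of the single- vs multi-modality comparison: each
    modality gets its own feature-graph (7 or 14 nodes) and its own GCN,
    all from one precomputed feature table.
    """
    cfg = config or PipelineConfig()
    out = {}
    for modality in ("eeg", "eye", "both"):
        res = run_pipeline_from_features(features, replace(cfg, modality=modality), seed)
        out[modality] = res.metrics
    return out
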