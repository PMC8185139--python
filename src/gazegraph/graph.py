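"""Multimodal feature graphs: 14-node vectors, covariance edges, batching.

Every sample (one EEG segment paired with its subject's eye-tracking
features) becomes a 14-node graph: EEG features at positions 1-7, eye
features at positions 8-14.  All sample graphs share one binary adjacency,
obtained by thresholding the absolute feature covariance computed on the
training samples; per-sample node attributes are the feature values.
Batches stack graphs block-diagonally so one matrix product propagates all
graphs at once with no cross-graph edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .eeg import EEG_FEATURE_NAMES, EEGFeatureSet
from .eye import TEST_NAMES, EyeFeatureSet

__all__ = [
    "NODE_NAMES",
    "FeatureVector",
    "FeatureGraph",
    "GraphBatch",
    "assemble_feature_vectors",
    "vectors_to_frame",
    "covariance_adjacency",
    "covariance_adjacency_from_matrix",
    "edge_density_table",
    "build_graphs",
    "batch_graphs",
    "unbatch_graphs",
]

#: Global node ordering: 7 EEG features then 7 eye-tracking features.
NODE_NAMES: tuple[str, ...] = EEG_FEATURE_NAMES + TEST_NAMES
N_NODES = len(NODE_NAMES)


@dataclass
class FeatureVector:
    """One sample's 14 ordered node attributes plus identifiers."""

    values: np.ndarray
    sample_id: str
    subject_id: str
    group: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ValueError(f"expected {N_NODES} values, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values in sample {self.sample_id}")


@dataclass
class FeatureGraph:
    """A named-node graph with scalar attributes and binary adjacency."""

    node_names: tuple[str, ...]
    attributes: np.ndarray  # (n,) node attribute values
    adjacency: np.ndarray  # (n, n) binary, symmetric, zero diagonal
    label: str | None = None

    def __post_init__(self) -> None:
        self.attributes = np.asarray(self.attributes, dtype=float)
        a = np.asarray(self.adjacency)
        n = len(self.node_names)
        if self.attributes.shape != (n,):
            raise ValueError("attributes must be one scalar per node")
        if a.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.diag(a).any():
            raise ValueError("adjacency must have zero diagonal (self-loops are added at normalization)")
        self.adjacency = a.astype(float)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


@dataclass
class GraphBatch:
    """Block-diagonal stack of same-size graphs for one forward pass."""

    adjacency: sp.csr_matrix  # (N*n, N*n) block-diagonal
    attributes: np.ndarray  # (N*n, 1) stacked node attributes
    membership: np.ndarray  # (N*n,) graph index of each row
    labels: list[str | None]
    node_names: tuple[str, ...]

    @property
    def n_graphs(self) -> int:
        return len(self.labels)

    @property
    def n_nodes_per_graph(self) -> int:
        return len(self.node_names)


def assemble_feature_vectors(
    eeg_features: Sequence[tuple[str, str, EEGFeatureSet]],
    eye_features: dict[str, EyeFeatureSet],
    groups: dict[str, str] | None = None,
) -> list[FeatureVector]:
    """Pair per-segment EEG features with per-subject eye features.

    Parameters
    ----------
    eeg_features : sequence of (subject_id, sample_id, EEGFeatureSet)
        One entry per EEG segment.
    eye_features : subject_id -> EyeFeatureSet
        Each subject's eye features are replicated into every one of that
        subject's sample vectors (positions 8-14).
    groups : optional subject_id -> group label.

    Raises
    ------
    KeyError listing every subject that has EEG samples but no eye features.
    """
    missing = sorted({s for s, _, _ in eeg_features} - set(eye_features))
    if missing:
        raise KeyError(f"no eye features for subject(s): {missing}")
    out = []
    for subject_id, sample_id, eeg in eeg_features:
        values = np.concatenate([eeg.as_array(), eye_features[subject_id].as_array()])
        out.append(
            FeatureVector(
                values=values,
                sample_id=sample_id,
                subject_id=subject_id,
                group=groups.get(subject_id) if groups else None,
            )
        )
    return out


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors as samples x (ids + 14 named columns)."""
    rows = [
        {"sample_id": v.sample_id, "subject_id": v.subject_id, "group": v.group}
        | dict(zip(NODE_NAMES, v.values))
        for v in vectors
    ]
    return pd.DataFrame(rows)


def covariance_adjacency_from_matrix(
    x: np.ndarray,
    names: Sequence[str],
    tau: float = 0.3,
    mode: Literal["absolute", "signed"] = "absolute",
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded-covariance adjacency from a samples x features matrix.

    Generic core of :func:`covariance_adjacency`; also used for the 7-node
    single-modality ablation graphs.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training vectors to estimate covariance")
    if x.shape[1] != len(names):
        raise ValueError("feature count does not match names")
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance feature(s) under standardization: {[names[i] for i in zero]}"
            )
        x = (x - x.mean(axis=0)) / sd
    cov = np.cov(x, rowvar=False, ddof=1)
    strength = np.abs(cov) if mode == "absolute" else cov
    adjacency = (strength > tau).astype(float)
    np.fill_diagonal(adjacency, 0.0)
    return cov, adjacency


def covariance_adjacency(
    training_vectors: Sequence[FeatureVector],
    tau: float = 0.3,
    mode: Literal["absolute", "signed"] = "absolute",
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared binary adjacency from thresholded feature covariance.

    The unbiased sample covariance of the 14 features is computed across
    the *training* vectors only (fitting it on all data would leak test
    information into the graph structure).  With ``standardize`` (default)
    features are z-scored first, so the covariance is the correlation
    matrix and ``tau`` is a correlation threshold.  An edge links features
    i != j when ``|cov(i, j)| > tau`` (absolute mode) or ``cov(i, j) > tau``
    (signed mode — the literal "covariance above threshold" reading).

    Returns
    -------
    (covariance, adjacency) : both (14, 14); adjacency is binary, symmetric,
        zero-diagonal, and is meant to be shared by every sample graph.
    """
    x = np.stack([v.values for v in training_vectors])  # samples x features
    return covariance_adjacency_from_matrix(x, NODE_NAMES, tau=tau, mode=mode, standardize=standardize)


def edge_density_table(
    training_vectors: Sequence[FeatureVector],
    taus: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0, 0.05), 2)),
    mode: Literal["absolute", "signed"] = "absolute",
) -> pd.DataFrame:
    """Edge density as a function of tau — a diagnostic for choosing tau."""
    rows = []
    n = N_NODES
    max_edges = n * (n - 1) / 2
    for tau in taus:
        _, a = covariance_adjacency(training_vectors, tau=tau, mode=mode)
        rows.append({"tau": float(tau), "n_edges": int(a.sum() // 2),
                     "density": float(a.sum() / 2 / max_edges)})
    return pd.DataFrame(rows)


def build_graphs(
    vectors: Sequence[FeatureVector], adjacency: np.ndarray
) -> list[FeatureGraph]:
    """Attach the shared adjacency to each sample's attribute vector."""
    return [
        FeatureGraph(
            node_names=NODE_NAMES,
            attributes=v.values,
            adjacency=adjacency,
            label=v.group,
        )
        for v in vectors
    ]


def batch_graphs(graphs: Sequence[FeatureGraph]) -> GraphBatch:
    """Stack graphs into one block-diagonal adjacency and attribute column.

    All graphs must share node count and ordering; membership row i // n
    maps stacked rows back to their graph.
    """
    if not graphs:
        raise ValueError("empty graph list")
    names = graphs[0].node_names
    if any(g.node_names != names for g in graphs):
        raise ValueError("all graphs must share node count and ordering")
    adj = sp.block_diag([sp.csr_matrix(g.adjacency) for g in graphs], format="csr")
    attributes = np.concatenate([g.attributes for g in graphs])[:, None]
    membership = np.repeat(np.arange(len(graphs)), len(names))
    return GraphBatch(
        adjacency=adj,
        attributes=attributes,
        membership=membership,
        labels=[g.label for g in graphs],
        node_names=names,
    )


def unbatch_graphs(batch: GraphBatch) -> list[FeatureGraph]:
    """Invert :func:`batch_graphs`."""
    n = batch.n_nodes_per_graph
    dense = batch.adjacency.toarray()
    out = []
    for g in range(batch.n_graphs):
        sl = slice(g * n, (g + 1) * n)
        out.append(
            FeatureGraph(
                node_names=batch.node_names,
                attributes=batch.attributes[sl, 0],
                adjacency=dense[sl, sl],
                label=batch.labels[g],
            )
        )
    return out
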