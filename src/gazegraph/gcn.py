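"""Two-weight-matrix graph convolutional network on batched feature graphs.

The model is the classic renormalized-adjacency GCN

    Z = softmax( A_hat . relu( A_hat . X . W0 ) . W1 ),

where A_hat = D^{-1/2} (A + I) D^{-1/2} is the symmetrically normalized
adjacency with self-loops (the renormalization trick keeps the spectral
radius at or below 1 and lets isolated nodes pass their own attribute
through).  Training minimizes the node-level cross-entropy over labeled
nodes by full-batch gradient descent with momentum, using the analytic
gradients of the two-layer model.  At inference a graph is scored by
mean-pooling its node probability rows and taking the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .graph import GraphBatch

__all__ = [
    "NormalizedAdjacency",
    "GCNParams",
    "TrainConfig",
    "normalize_adjacency",
    "gcn_forward",
    "cross_entropy_loss",
    "loss_gradients",
    "train_gcn",
    "save_params",
    "load_params",
    "predict_graphs",
]

_EPS = np.finfo(float).tiny  # probability floor inside log


@dataclass
class NormalizedAdjacency:
    """D^{-1/2} (A [+ I]) D^{-1/2} and the degrees used to build it."""

    matrix: sp.csr_matrix
    degrees: np.ndarray


@dataclass
class GCNParams:
    """The two weight matrices: input->hidden (W0) and hidden->classes (W1)."""

    w0: np.ndarray
    w1: np.ndarray

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=float)
        self.w1 = np.asarray(self.w1, dtype=float)
        if self.w0.ndim != 2 or self.w1.ndim != 2 or self.w0.shape[1] != self.w1.shape[0]:
            raise ValueError(
                f"inconsistent shapes: W0 {self.w0.shape}, W1 {self.w1.shape}"
            )

    @property
    def hidden(self) -> int:
        return self.w0.shape[1]

    @property
    def n_classes(self) -> int:
        return self.w1.shape[1]


@dataclass
class TrainConfig:
    """Optimization settings; every random draw is governed by ``seed``."""

    learning_rate: float = 0.01
    epochs: int = 200
    seed: int = 0
    hidden: int = 16
    momentum: float = 0.9
    init_scale: float | None = None  # None -> Glorot-uniform limit
    pooling: Literal["all-nodes-labeled", "mean-pool"] = "all-nodes-labeled"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def normalize_adjacency(
    adjacency: sp.spmatrix | np.ndarray, add_self_loops: bool = True
) -> NormalizedAdjacency:
    """Symmetric degree normalization of a (block-diagonal) adjacency.

    With self-loops (default) every node has degree >= 1 and isolated
    nodes map to themselves; without, a zero-degree node is an error.
    Block structure is preserved, so batched graphs stay decoupled.
    """
    a = sp.csr_matrix(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if (abs(a - a.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if add_self_loops:
        a = a + sp.identity(a.shape[0], format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        raise ValueError(f"zero-degree node(s) at index {zero.tolist()}; enable self-loops")
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return NormalizedAdjacency(matrix=(d_inv_sqrt @ a @ d_inv_sqrt).tocsr(), degrees=deg)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(
    x: np.ndarray, adj: NormalizedAdjacency, params: GCNParams
) -> np.ndarray:
    """Node-level class probabilities Z; each row sums to 1."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != adj.matrix.shape[0] or x.shape[1] != params.w0.shape[0]:
        raise ValueError(
            f"shape mismatch: X {x.shape}, adjacency {adj.matrix.shape}, W0 {params.w0.shape}"
        )
    h = np.maximum(adj.matrix @ (x @ params.w0), 0.0)
    return _softmax(adj.matrix @ (h @ params.w1))


def cross_entropy_loss(
    z: np.ndarray, labels_onehot: np.ndarray, labeled_idx: np.ndarray | None = None
) -> float:
    """Summed cross-entropy over the labeled node set.

    ``labels_onehot`` has one-hot rows for the labeled nodes (aligned with
    ``labeled_idx``, or with all rows of ``z`` when it is None).  Zero
    predicted probabilities at a labeled class are floored at the smallest
    positive double before the log, so the loss stays finite.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(labels_onehot, dtype=float)
    rows = z if labeled_idx is None else z[np.asarray(labeled_idx)]
    if rows.shape != y.shape:
        raise ValueError(f"shape mismatch: Z rows {rows.shape}, labels {y.shape}")
    return float(-(y * np.log(np.maximum(rows, _EPS))).sum())


def loss_gradients(
    x: np.ndarray,
    adj: NormalizedAdjacency,
    params: GCNParams,
    labels_onehot: np.ndarray,
    labeled_idx: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its analytic gradients w.r.t. W0 and W1.

    Uses the softmax + cross-entropy identity dL/dlogits = Z - Y on labeled
    rows (zero elsewhere) and backpropagates through the two propagation
    steps; A_hat is symmetric so its transpose products reuse the matrix.
    """
    a = adj.matrix
    x = np.asarray(x, dtype=float)
    pre = a @ (x @ params.w0)
    h = np.maximum(pre, 0.0)
    z = _softmax(a @ (h @ params.w1))

    y_full = np.zeros_like(z)
    idx = np.arange(z.shape[0]) if labeled_idx is None else np.asarray(labeled_idx)
    y_full[idx] = labels_onehot
    d_logits = np.zeros_like(z)
    d_logits[idx] = z[idx] - labels_onehot

    loss = cross_entropy_loss(z, labels_onehot, labeled_idx)
    back = a @ d_logits  # A_hat^T = A_hat
    grad_w1 = h.T @ back
    d_h = back @ params.w1.T
    d_pre = d_h * (pre > 0)
    grad_w0 = x.T @ (a @ d_pre)
    return loss, grad_w0, grad_w1


def _init_params(n_features: int, cfg: TrainConfig, n_classes: int = 2) -> GCNParams:
    rng = np.random.default_rng(cfg.seed)

    def glorot(shape):
        limit = cfg.init_scale
        if limit is None:
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    return GCNParams(w0=glorot((n_features, cfg.hidden)), w1=glorot((cfg.hidden, n_classes)))


def _onehot(labels: list[str], classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        y[i, index[lab]] = 1.0
    return y


def train_gcn(
    batch: GraphBatch,
    adj: NormalizedAdjacency,
    cfg: TrainConfig | None = None,
) -> tuple[GCNParams, list[str], np.ndarray]:
    """Fit the two weight matrices on a labeled graph batch.

    In the default "all-nodes-labeled" mode every node of a training graph
    carries its graph's label, matching the node-level cross-entropy loss
    literally; "mean-pool" mode instead averages each graph's node
    probabilities before the loss.  Full-batch gradient descent with
    momentum minimizes the cross-entropy normalized per labeled row (so the
    step size is independent of how many graphs are batched); deterministic
    for a fixed config seed.

    Returns
    -------
    (params, classes, loss_trace) : fitted weights, the sorted class label
        order used for one-hot encoding, and the per-epoch mean loss.
    """
    cfg = cfg or TrainConfig()
    if any(lab is None for lab in batch.labels):
        raise ValueError("every graph in a training batch needs a label")
    classes = sorted(set(batch.labels))
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {classes}")
    n = batch.n_nodes_per_graph
    if cfg.pooling == "all-nodes-labeled":
        node_labels = [batch.labels[g] for g in batch.membership]
        y = _onehot(node_labels, classes)
        labeled_idx = None
    else:
        y = _onehot(list(batch.labels), classes)
        labeled_idx = None  # handled via pooling matrix below

    params = _init_params(batch.attributes.shape[1], cfg, n_classes=len(classes))
    vel_w0 = np.zeros_like(params.w0)
    vel_w1 = np.zeros_like(params.w1)
    # mean-pool mode: P averages node rows per graph; gradients flow through P
    pool = None
    if cfg.pooling == "mean-pool":
        n_graphs = batch.n_graphs
        pool = sp.csr_matrix(
            (np.full(len(batch.membership), 1.0 / n), (batch.membership, np.arange(len(batch.membership)))),
            shape=(n_graphs, len(batch.membership)),
        )

    trace = np.empty(cfg.epochs)
    x = batch.attributes
    a = adj.matrix
    # optimize the mean cross-entropy per labeled row: keeps the gradient
    # magnitude independent of batch size so one learning rate serves any N
    scale = 1.0 / y.shape[0]
    for epoch in range(cfg.epochs):
        if pool is None:
            loss, g0, g1 = loss_gradients(x, adj, params, y, labeled_idx)
        else:
            # forward with pooled logits
            pre = a @ (x @ params.w0)
            h = np.maximum(pre, 0.0)
            logits = pool @ (a @ (h @ params.w1))
            z = _softmax(logits)
            loss = float(-(y * np.log(np.maximum(z, _EPS))).sum())
            d_logits = z - y
            back = a @ (pool.T @ d_logits)
            g1 = h.T @ back
            d_pre = (back @ params.w1.T) * (pre > 0)
            g0 = x.T @ (a @ d_pre)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = loss * scale
        vel_w0 = cfg.momentum * vel_w0 - cfg.learning_rate * scale * g0
        vel_w1 = cfg.momentum * vel_w1 - cfg.learning_rate * scale * g1
        params.w0 = params.w0 + vel_w0
        params.w1 = params.w1 + vel_w1
    return params, classes, trace


def save_params(
    params: GCNParams, path, config: TrainConfig | None = None
) -> None:
    """Serialize weights as a portable JSON archive (shapes + flat arrays),
    echoing the training config when given."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    payload = {
        "w0": {"shape": list(params.w0.shape), "data": params.w0.ravel().tolist()},
        "w1": {"shape": list(params.w1.shape), "data": params.w1.ravel().tolist()},
        "config": asdict(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path) -> tuple[GCNParams, dict | None]:
    """Inverse of :func:`save_params`; returns (params, config echo)."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    w0 = np.array(payload["w0"]["data"]).reshape(payload["w0"]["shape"])
    w1 = np.array(payload["w1"]["data"]).reshape(payload["w1"]["shape"])
    return GCNParams(w0=w0, w1=w1), payload["config"]


def predict_graphs(
    z: np.ndarray, membership: np.ndarray, classes: list[str] | None = None
) -> list:
    """Graph-level decisions from node probabilities.

    Each graph's node probability rows are averaged (mean-pool readout) and
    the argmax class taken; an exact tie resolves to the lower class index.
    """
    membership = np.asarray(membership)
    if membership.shape[0] != z.shape[0]:
        raise ValueError("membership length must match Z rows")
    n_graphs = membership.max() + 1
    out = []
    for g in range(n_graphs):
        rows = z[membership == g]
        if rows.size == 0:
            raise ValueError(f"graph {g} has no nodes")
        mean = rows.mean(axis=0)
        cls = int(np.argmax(mean))  # argmax takes the lower index on ties
        out.append(classes[cls] if classes is not None else cls)
    return out
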