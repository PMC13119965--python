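"""Two-layer graph-attention node classifier trained with focal loss.

Layer 1 uses two attention heads (per-head width 128, concatenated to 256),
layer 2 a single head of width 64 without concatenation; batch-norm, ReLU
and dropout 0.4 sit between, and an affine readout maps the 64-d node
representations to class scores. Attention is the additive form: per head,
e_ij = LeakyReLU(a_l . W h_i + a_r . W h_j) over j in N(i) u {i}, normalized
by a softmax whose exponentiated scores are multiplied by the (nonnegative
part of the) edge weight, self-loops weighing 1 — so cohesion-boosted edge
weights are consequential. A plain graph-convolution layer (symmetric-
normalized adjacency) is retained for ablation.

Training: Adam, early stopping on validation balanced accuracy, and a
learning-rate x top-K grid search mirroring the published search space.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from ._autodiff import DTYPE, Tensor, concat
from .datatypes import FeatureMatrix
from .evaluation import balanced_accuracy, confusion
from .graph import GraphConfig, SampleGraph, build_graph

__all__ = [
    "VGCNConfig",
    "VGCNModel",
    "focal_loss",
    "gcn_layer_dense",
    "train_vgcn",
    "grid_search",
    "predict",
]

DEFAULT_LR_GRID = (1e-4, 3e-4, 5e-4, 1e-3, 3e-3)
DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class VGCNConfig:
    in_dim: int = 100
    n_classes: int = 3
    heads1: int = 2
    out1: int = 128  # per-head; concatenated -> heads1 * out1
    out2: int = 64
    dropout: float = 0.4
    focal_alpha: float = 1.0
    focal_gamma: float = 2.0
    learning_rate: float = 0.003
    epochs: int = 100
    early_stop_patience: int = 35
    seed: int = 0
    use_edge_weights: bool = True
    leaky_slope: float = 0.2

    def __post_init__(self):
        for name in ("in_dim", "n_classes", "heads1", "out1", "out2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")
        if self.focal_gamma < 0:
            raise ValueError(f"focal_gamma must be >= 0, got {self.focal_gamma}")
        if self.focal_alpha <= 0:
            raise ValueError(f"focal_alpha must be > 0, got {self.focal_alpha}")


def _directed_edges(g: SampleGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both directions of every undirected edge plus unit self-loops.

    Returns (src, dst, weight); negative weights are floored at 0 so the
    attention denominator (which always contains the unit self-loop term)
    stays positive.
    """
    e = g.edges
    w = np.maximum(g.weights, 0.0)
    not_self = e[:, 0] != e[:, 1]
    e = e[not_self]
    w = w[not_self]
    src = np.concatenate([e[:, 0], e[:, 1], np.arange(g.n)])
    dst = np.concatenate([e[:, 1], e[:, 0], np.arange(g.n)])
    weight = np.concatenate([w, w, np.ones(g.n)])
    return src, dst, weight


class GATLayer(_nn.Module):
    """Multi-head additive-attention message passing."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        heads: int,
        concat_heads: bool,
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
    ):
        self.heads = heads
        self.concat_heads = concat_heads
        self.leaky_slope = leaky_slope
        self.W = [
            Tensor(_nn._he_uniform(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
            for _ in range(heads)
        ]
        self.a_src = [
            Tensor(_nn._he_uniform(rng, out_dim, (out_dim, 1)), requires_grad=True)
            for _ in range(heads)
        ]
        self.a_dst = [
            Tensor(_nn._he_uniform(rng, out_dim, (out_dim, 1)), requires_grad=True)
            for _ in range(heads)
        ]

    def parameters(self):
        return list(self.W) + list(self.a_src) + list(self.a_dst)

    def __call__(
        self,
        h: Tensor,
        src: np.ndarray,
        dst: np.ndarray,
        edge_w: np.ndarray | None,
        n: int,
    ) -> Tensor:
        """Anchor i attends over its in-neighborhood {j : (src=j, dst=i)}."""
        outs = []
        for head in range(self.heads):
            Wh = h @ self.W[head]
            s_anchor = (Wh @ self.a_dst[head]).reshape(-1)  # score of the anchor term
            s_neigh = (Wh @ self.a_src[head]).reshape(-1)  # score of the neighbor term
            e = (s_anchor.take(dst) + s_neigh.take(src)).leaky_relu(self.leaky_slope)
            # numerically stable per-anchor softmax
            shift = np.zeros(n, dtype=DTYPE)
            np.maximum.at(shift, dst, e.data)
            ex = (e - Tensor(shift[dst])).exp()
            if edge_w is not None:
                ex = ex * Tensor(edge_w.astype(DTYPE))
            denom = ex.segment_sum(dst, n)
            alpha = ex / denom.take(dst)
            msgs = Wh.take(src) * alpha.reshape(-1, 1)
            outs.append(msgs.segment_sum(dst, n))
        if self.concat_heads:
            return concat(outs, axis=1)
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return acc * DTYPE(1.0 / self.heads)


def gcn_layer_dense(
    H: np.ndarray, g: SampleGraph, W: np.ndarray, norm: str = "sym"
) -> np.ndarray:
    """Plain graph-convolution layer for ablation (no nonlinearity).

    ``norm='sym'``: H' = D^-1/2 (A+I) D^-1/2 H W (the classic symmetric
    normalization); ``norm='row'``: H' = D^-1 (A+I) H W, a neighborhood
    average for which constant node features are a fixed point when W = I.
    """
    A = np.zeros((g.n, g.n))
    src, dst, w = _directed_edges(g)
    A[dst, src] = w
    deg = A.sum(axis=1)
    safe = np.where(deg > 0, deg, 1.0)
    if norm == "sym":
        dinv = 1.0 / np.sqrt(safe)
        An = dinv[:, None] * A * dinv[None, :]
    elif norm == "row":
        An = A / safe[:, None]
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return An @ np.asarray(H) @ np.asarray(W)


class _GATNet(_nn.Module):
    def __init__(self, cfg: VGCNConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.gat1 = GATLayer(cfg.in_dim, cfg.out1, cfg.heads1, True, rng, cfg.leaky_slope)
        self.bn = _nn.BatchNorm1d(cfg.heads1 * cfg.out1)
        self.gat2 = GATLayer(
            cfg.heads1 * cfg.out1, cfg.out2, 1, False, rng, cfg.leaky_slope
        )
        self.readout = _nn.Dense(cfg.out2, cfg.n_classes, rng)

    def parameters(self):
        return (
            self.gat1.parameters()
            + self.bn.parameters()
            + self.gat2.parameters()
            + self.readout.parameters()
        )

    def forward(
        self,
        X: np.ndarray,
        src: np.ndarray,
        dst: np.ndarray,
        edge_w: np.ndarray | None,
        training: bool,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        cfg = self.cfg
        n = X.shape[0]
        h = Tensor(np.asarray(X, dtype=DTYPE))
        h = _nn.dropout(h, cfg.dropout, rng, training)
        h = self.gat1(h, src, dst, edge_w, n)
        h = self.bn(h, training).relu()
        h = _nn.dropout(h, cfg.dropout, rng, training)
        h = self.gat2(h, src, dst, edge_w, n)
        return self.readout(h.relu())


@dataclass
class VGCNModel:
    config: VGCNConfig
    net: _GATNet
    history: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    def forward(self, g: SampleGraph, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if g.node_features.shape[1] != self.config.in_dim:
            raise ValueError(
                f"node feature width {g.node_features.shape[1]} != in_dim "
                f"{self.config.in_dim}"
            )
        src, dst, w = _directed_edges(g)
        edge_w = w if self.config.use_edge_weights else None
        scores = self.net.forward(g.node_features, src, dst, edge_w, training, rng)
        return scores if training else np.asarray(scores.data, dtype=float)


def build_vgcn(cfg: VGCNConfig) -> VGCNModel:
    return VGCNModel(config=cfg, net=_GATNet(cfg, np.random.default_rng(cfg.seed)))


def focal_loss(scores, labels, alpha: float = 1.0, gamma: float = 2.0) -> Tensor:
    """Mean of -alpha (1 - p_t)^gamma log p_t; gamma=0 is cross-entropy."""
    scores = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores, dtype=DTYPE))
    labels = np.asarray(labels, dtype=int)
    lp = _nn.log_softmax(scores)
    onehot = np.zeros(lp.shape, dtype=DTYPE)
    onehot[np.arange(len(labels)), labels] = 1.0
    logp_t = (lp * Tensor(onehot)).sum(axis=1)
    if gamma == 0:
        return -(logp_t.mean()) * DTYPE(alpha)
    p_t = logp_t.exp()
    focus = (DTYPE(1.0) - p_t + DTYPE(1e-12)) ** gamma
    return -((focus * logp_t).mean()) * DTYPE(alpha)


def train_vgcn(
    model: VGCNModel,
    train_g: SampleGraph,
    val_g: SampleGraph,
    val_labels: np.ndarray | None = None,
) -> VGCNModel:
    """Adam + focal loss with early stopping on validation balanced accuracy.

    Validation labels are used only for the stopping metric; parameters from
    the best-validation epoch are restored.
    """
    cfg = model.config
    if train_g.labels is None:
        raise ValueError("training graph must carry labels")
    y_train = np.asarray(train_g.labels, dtype=int)
    y_val = np.asarray(val_labels if val_labels is not None else val_g.labels, dtype=int)
    rng = np.random.default_rng(cfg.seed + 7)
    opt = _nn.Adam(model.net.parameters(), cfg.learning_rate)
    src, dst, w = _directed_edges(train_g)
    edge_w = w if cfg.use_edge_weights else None

    best_bac = -np.inf
    best_params = None
    since_improve = 0
    for epoch in range(cfg.epochs):
        scores = model.net.forward(train_g.node_features, src, dst, edge_w, True, rng)
        loss = focal_loss(scores, y_train, cfg.focal_alpha, cfg.focal_gamma)
        opt.zero_grad()
        loss.backward()
        opt.step()

        val_scores = model.forward(val_g, training=False)
        val_pred = val_scores.argmax(axis=1)
        val_bac = balanced_accuracy(confusion(y_val, val_pred, cfg.n_classes))
        model.history.append(
            {"epoch": epoch, "train_loss": float(loss.data), "val_bac": val_bac}
        )
        if val_bac > best_bac:
            best_bac = val_bac
            best_params = [p.data.copy() for p in model.net.parameters()]
            best_norm_state = model.net.norm_state()
            model.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > cfg.early_stop_patience:
                break
    if best_params is not None:
        for p, arr in zip(model.net.parameters(), best_params):
            p.data[...] = arr
        model.net.set_norm_state(best_norm_state)
    return model


def predict(model: VGCNModel, g: SampleGraph) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels (ties -> lowest class index) + softmax probabilities."""
    scores = model.forward(g, training=False)
    shifted = scores - scores.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    return scores.argmax(axis=1), probs


def grid_search(
    train_fm: FeatureMatrix,
    val_fm: FeatureMatrix,
    y_train: np.ndarray,
    y_val: np.ndarray,
    base_cfg: VGCNConfig,
    graph_cfg: GraphConfig,
    lr_grid=DEFAULT_LR_GRID,
    k_grid=DEFAULT_K_GRID,
) -> tuple[tuple[float, int], pd.DataFrame]:
    """Validation-BAC grid over learning rate (rows) x top-K (columns).

    Graphs are rebuilt for every K; ties resolve to the first cell in scan
    order (lr outer, K inner). Returns ((best_lr, best_k), BAC table).
    """
    if not len(lr_grid) or not len(k_grid):
        raise ValueError("grids must be nonempty")
    table = pd.DataFrame(index=list(lr_grid), columns=list(k_grid), dtype=float)
    best = (-np.inf, None)
    from dataclasses import replace

    for lr in lr_grid:
        for k in k_grid:
            gcfg = replace(graph_cfg, top_k=int(k))
            tg = build_graph(train_fm, y_train, gcfg)
            vg = build_graph(val_fm, None, gcfg)
            cfg = replace(base_cfg, learning_rate=float(lr))
            model = build_vgcn(cfg)
            train_vgcn(model, tg, vg, val_labels=y_val)
            bac = max(h["val_bac"] for h in model.history)
            table.loc[lr, k] = bac
            if bac > best[0]:
                best = (bac, (float(lr), int(k)))
    return best[1], table
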