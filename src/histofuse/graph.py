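"""Cosine-similarity sample graphs with top-K connectivity.

Each sample becomes a node; each node is joined to its K most similar
neighbors by cosine similarity, union-symmetrized. On the training graph,
same-class similarities receive a small additive cohesion boost (clipped at
1) before neighbor selection, so class structure shapes the topology and not
just the edge weights. Validation/test graphs carry no labels and no boost.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import FeatureMatrix

__all__ = ["GraphConfig", "SampleGraph", "cosine_matrix", "build_graph", "graph_stats"]


@dataclass(frozen=True)
class GraphConfig:
    top_k: int = 15
    cohesion_delta: float = 0.05  # additive, train graph only
    boost_stage: str = "pre_topk"  # or "post_topk"
    include_self_loops: bool = False
    symmetrize: str = "union"

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.cohesion_delta < 0:
            raise ValueError(f"cohesion_delta must be >= 0, got {self.cohesion_delta}")
        if self.boost_stage not in ("pre_topk", "post_topk"):
            raise ValueError(f"unknown boost_stage {self.boost_stage!r}")
        if self.symmetrize != "union":
            raise ValueError("only union symmetrization is supported")


@dataclass
class SampleGraph:
    """Undirected weighted sample graph with node features."""

    n: int
    edges: np.ndarray  # (m, 2) int, i < j, unique
    weights: np.ndarray  # (m,) float
    node_features: np.ndarray  # (n, d)
    labels: np.ndarray | None = None  # training graph only

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("edge weights must be finite")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for col in (0, 1):
            np.add.at(deg, self.edges[:, col], 1)
        # self-loops contribute a single endpoint twice; count once
        self_loops = self.edges[:, 0] == self.edges[:, 1]
        deg -= np.bincount(self.edges[self_loops, 0], minlength=self.n)
        return deg

    def save(self, edge_path: str | os.PathLike, node_path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"i": self.edges[:, 0], "j": self.edges[:, 1], "weight": self.weights}
        ).to_csv(os.fspath(edge_path), sep="\t", index=False)
        df = pd.DataFrame(
            self.node_features, columns=[f"x{k}" for k in range(self.node_features.shape[1])]
        )
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(os.fspath(node_path), index=False)

    @classmethod
    def load(cls, edge_path: str | os.PathLike, node_path: str | os.PathLike) -> "SampleGraph":
        ed = pd.read_csv(os.fspath(edge_path), sep="\t")
        nd = pd.read_csv(os.fspath(node_path))
        labels = nd.pop("label").to_numpy() if "label" in nd.columns else None
        X = nd.to_numpy(dtype=float)
        return cls(
            n=len(nd),
            edges=ed[["i", "j"]].to_numpy(),
            weights=ed["weight"].to_numpy(),
            node_features=X,
            labels=labels,
        )


def cosine_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities; symmetric with unit diagonal."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm feature row(s) at index {zero.tolist()}")
    U = X / norms[:, None]
    S = U @ U.T
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def build_graph(
    fm: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None,
    cfg: GraphConfig,
) -> SampleGraph:
    """Top-K cosine graph; class-cohesion boost applied when labels given."""
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("graph construction needs at least 2 samples")
    k = cfg.top_k
    if k >= n:
        warnings.warn(f"top_k={k} >= n={n}; clamped to {n - 1}")
        k = n - 1

    S = cosine_matrix(X)
    boosted = S.copy()
    if labels is not None and cfg.cohesion_delta > 0:
        labels = np.asarray(labels)
        same = labels[:, None] == labels[None, :]
        boosted = np.where(same, np.minimum(S + cfg.cohesion_delta, 1.0), S)

    S_rank = boosted if cfg.boost_stage == "pre_topk" else S
    S_weight = boosted

    pairs = set()
    order_matrix = np.argsort(-S_rank, axis=1, kind="stable")
    for i in range(n):
        neighbors = [j for j in order_matrix[i] if j != i][:k]
        for j in neighbors:
            pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=int)
    weights = S_weight[edges[:, 0], edges[:, 1]]

    if cfg.include_self_loops:
        self_edges = np.stack([np.arange(n), np.arange(n)], axis=1)
        edges = np.concatenate([edges, self_edges])
        weights = np.concatenate([weights, np.ones(n)])

    return SampleGraph(n=n, edges=edges, weights=weights, node_features=X, labels=labels)


def graph_stats(g: SampleGraph) -> dict:
    """Deterministic summary: degree distribution, weight range, components."""
    deg = g.degrees()
    adj = coo_matrix(
        (np.ones(len(g.edges)), (g.edges[:, 0], g.edges[:, 1])), shape=(g.n, g.n)
    )
    n_comp = connected_components(adj, directed=False)[0]
    return {
        "n_nodes": g.n,
        "n_edges": len(g.edges),
        "min_degree": int(deg.min()),
        "max_degree": int(deg.max()),
        "mean_degree": float(deg.mean()),
        "weight_min": float(g.weights.min()) if len(g.weights) else float("nan"),
        "weight_max": float(g.weights.max()) if len(g.weights) else float("nan"),
        "n_components": int(n_comp),
    }
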