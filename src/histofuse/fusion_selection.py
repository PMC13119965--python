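"""Feature fusion and minimum-redundancy-maximum-relevance selection.

The three refined feature sets are concatenated column-wise, then the top-m
columns are chosen by greedy forward mRMR: step 1 takes the feature with the
largest mutual information I(f; c) with the class; every later step takes the
feature maximizing relevance penalized by its mean mutual information with
the already-selected set — as a quotient (MIQ, the default) or a difference
(MID). Mutual information is the plug-in estimate on equal-frequency
discretized columns, in nats.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "fuse",
    "mutual_information",
    "mrmr_rank",
    "apply_selection",
]


@dataclass(frozen=True)
class SelectionConfig:
    n_select: int = 100
    criterion: str = "MIQ"  # MIQ (quotient) or MID (difference)
    n_bins: int = 10
    epsilon: float = 1e-12
    branch_order: tuple[str, ...] = ("simclr", "deepcluster", "byol")

    def __post_init__(self):
        if self.n_select < 1:
            raise ValueError(f"n_select must be >= 1, got {self.n_select}")
        if self.criterion not in ("MIQ", "MID"):
            raise ValueError(f"criterion must be MIQ or MID, got {self.criterion!r}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")


@dataclass
class SelectionResult:
    """Ranked selection with per-step diagnostics and column provenance."""

    indices: list[int]
    relevance: list[float]
    redundancy: list[float]
    score: list[float]
    provenance: list[str]
    criterion: str
    n_bins: int

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(
                {
                    "indices": self.indices,
                    "relevance": self.relevance,
                    "redundancy": self.redundancy,
                    "score": self.score,
                    "provenance": self.provenance,
                    "criterion": self.criterion,
                    "n_bins": self.n_bins,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SelectionResult":
        with open(os.fspath(path)) as fh:
            return cls(**json.load(fh))


def fuse(
    branch_outputs: list[FeatureMatrix],
    branch_names: list[str] | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation of aligned feature sets.

    Row counts (and labels, when present) must agree; column names are
    prefixed with the branch name to record provenance.
    """
    if not branch_outputs:
        raise ValueError("need at least one branch")
    if branch_names is None:
        branch_names = [f"branch{i}" for i in range(len(branch_outputs))]
    first = branch_outputs[0]
    for fm in branch_outputs[1:]:
        if fm.n != first.n:
            raise ValueError(
                f"row count mismatch: {fm.n} vs {first.n}; branches must be aligned"
            )
        if not np.array_equal(fm.labels, first.labels):
            raise ValueError("branch label vectors differ; sample order misaligned")
    X = np.concatenate([fm.X for fm in branch_outputs], axis=1)
    names = [
        f"{bn}:{fn}"
        for bn, fm in zip(branch_names, branch_outputs)
        for fn in fm.feature_names
    ]
    return FeatureMatrix(X, first.labels, first.groups, names)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; categorical-like inputs pass through."""
    x = np.asarray(x)
    if x.dtype.kind in "OUSb":  # strings / objects: categorical
        return np.unique(x, return_inverse=True)[1]
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(x, y, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) on the discretized contingency table."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    return _mi_discrete(_discretize(x, n_bins), _discretize(y, n_bins))


def _mi_discrete(xb: np.ndarray, yb: np.ndarray) -> float:
    nx = int(xb.max()) + 1 if len(xb) else 1
    ny = int(yb.max()) + 1 if len(yb) else 1
    joint = np.bincount(xb * ny + yb, minlength=nx * ny).reshape(nx, ny)
    n = joint.sum()
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float((pj[nz] * np.log(pj[nz] / (px @ py)[nz])).sum())


def mrmr_rank(
    fm: FeatureMatrix,
    cfg: SelectionConfig | None = None,
    labels: np.ndarray | None = None,
) -> SelectionResult:
    """Greedy forward mRMR ranking of ``cfg.n_select`` columns.

    Ties break to the lowest column index. Redundancy of a candidate is its
    mean MI with the already-selected set; the MIQ denominator is guarded by
    ``cfg.epsilon``.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(labels if labels is not None else fm.labels)
    d = fm.d
    if cfg.n_select > d:
        raise ValueError(f"n_select={cfg.n_select} exceeds {d} available columns")

    cols = [_discretize(fm.X[:, j], cfg.n_bins) for j in range(d)]
    yb = _discretize(y, cfg.n_bins)
    relevance = np.array([_mi_discrete(c, yb) for c in cols])

    selected: list[int] = []
    red_sum = np.zeros(d)
    remaining = np.ones(d, dtype=bool)
    rel_out, red_out, score_out = [], [], []

    for step in range(cfg.n_select):
        if step == 0:
            scores = np.where(remaining, relevance, -np.inf)
            red = np.zeros(d)
        else:
            red = red_sum / step
            if cfg.criterion == "MID":
                scores = relevance - red
            else:
                scores = relevance / (red + cfg.epsilon)
            scores = np.where(remaining, scores, -np.inf)
        j = int(np.argmax(scores))  # argmax takes the lowest index on ties
        selected.append(j)
        remaining[j] = False
        rel_out.append(float(relevance[j]))
        red_out.append(float(red[j]))
        score_out.append(float(scores[j]))
        if step < cfg.n_select - 1:
            for i in np.flatnonzero(remaining):
                red_sum[i] += _mi_discrete(cols[i], cols[j])

    return SelectionResult(
        indices=selected,
        relevance=rel_out,
        redundancy=red_out,
        score=score_out,
        provenance=[fm.feature_names[j] for j in selected],
        criterion=cfg.criterion,
        n_bins=cfg.n_bins,
    )


def apply_selection(fm: FeatureMatrix, result: SelectionResult) -> FeatureMatrix:
    """Subset columns in ranked order; reuse the train-fit index list on any
    split of equal width."""
    if max(result.indices) >= fm.d:
        raise ValueError(
            f"selection index {max(result.indices)} out of range for {fm.d} columns"
        )
    return fm.subset_cols(result.indices)
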