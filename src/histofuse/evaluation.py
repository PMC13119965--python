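"""Splitting, metrics, cross-validation and separability diagnostics.

Splits are stratified and patient-aware: whole groups (all images from one
patient/slide) are greedily assigned to the partition with the largest
remaining per-class deficit, so no group ever straddles partitions and class
proportions are approximately preserved. Balanced accuracy (mean per-class
recall) is the headline metric; precision/recall/F1 are support-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .datatypes import FeatureMatrix

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "split",
    "confusion",
    "balanced_accuracy",
    "weighted_prf",
    "metrics_report",
    "cross_validate",
    "paired_t_test",
    "separability_report",
]


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, ...] = (0.70, 0.15, 0.15)
    stratified: bool = True
    group_aware: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")


def _greedy_group_assign(
    labels: np.ndarray,
    groups: np.ndarray,
    fractions: np.ndarray,
    stratified: bool,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Assign whole groups to partitions by largest remaining class deficit."""
    classes, y = np.unique(labels, return_inverse=True)
    n_classes = len(classes) if stratified else 1
    if not stratified:
        y = np.zeros(len(labels), dtype=int)
    group_names, g = np.unique(groups, return_inverse=True)
    n_parts = len(fractions)

    class_counts = np.bincount(y, minlength=n_classes).astype(float)
    targets = fractions[:, None] * class_counts[None, :]  # (parts, classes)
    current = np.zeros_like(targets)

    # per-group class composition
    comp = np.zeros((len(group_names), n_classes))
    np.add.at(comp, g, np.eye(n_classes)[y])

    sizes = comp.sum(axis=1)
    if sizes.max() > fractions.max() * len(labels) + 1e-9:
        raise ValueError(
            "unsatisfiable split: one group holds more samples than the "
            "largest partition fraction allows"
        )

    order = rng.permutation(len(group_names))
    order = order[np.argsort(-sizes[order], kind="stable")]  # big groups first

    assignment = np.empty(len(group_names), dtype=int)
    denom = np.maximum(targets, 1e-9)
    for gi in order:
        # relative deficit: fraction of each partition's per-class quota still
        # unfilled, weighted by the group's class composition
        deficits = ((targets - current) / denom * comp[gi][None, :]).sum(axis=1)
        part = int(np.argmax(deficits))
        assignment[gi] = part
        current[part] += comp[gi]

    part_of_sample = assignment[g]
    return [np.flatnonzero(part_of_sample == p) for p in range(n_parts)]


def split(
    labels: np.ndarray,
    groups: np.ndarray | None,
    spec: SplitSpec,
) -> tuple[np.ndarray, ...]:
    """Partition sample indices into train/val/test (per ``spec.fractions``)."""
    labels = np.asarray(labels)
    n = len(labels)
    if groups is None or not spec.group_aware:
        groups = np.arange(n).astype(str)  # singleton groups
    else:
        groups = np.asarray(groups)
        if len(groups) != n:
            raise ValueError("groups must cover all samples")
    rng = np.random.default_rng(spec.seed)
    parts = _greedy_group_assign(
        labels, groups, np.asarray(spec.fractions, dtype=float), spec.stratified, rng
    )
    return tuple(parts)


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0
        or y_true.max() >= n_classes
        or y_pred.min() < 0
        or y_pred.max() >= n_classes
    ):
        raise ValueError("labels out of range")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def balanced_accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("confusion matrix has an empty true class")
    return float(np.mean(np.diag(cm) / row_sums))


def weighted_prf(cm: np.ndarray) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 from a confusion matrix.

    Zero-division (class never predicted, or zero P+R) contributes 0 with a
    warning.
    """
    cm = np.asarray(cm, dtype=float)
    support = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    tp = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        rec = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    if np.any(pred_tot == 0):
        warnings.warn("a class is never predicted; its precision set to 0")
    w = support / support.sum()
    return float(w @ prec), float(w @ rec), float(w @ f1)


@dataclass
class MetricsReport:
    confusion_matrix: np.ndarray
    bac: float
    precision: float
    recall: float
    f1: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    n_per_class: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "bac": self.bac,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "n_per_class": self.n_per_class.tolist(),
        }


def metrics_report(y_true, y_pred, n_classes: int) -> MetricsReport:
    cm = confusion(y_true, y_pred, n_classes)
    cmf = cm.astype(float)
    support = cmf.sum(axis=1)
    pred_tot = cmf.sum(axis=0)
    tp = np.diag(cmf)
    prec = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
    rec = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    wp, wr, wf = weighted_prf(cm)
    return MetricsReport(
        confusion_matrix=cm,
        bac=balanced_accuracy(cm),
        precision=wp,
        recall=wr,
        f1=wf,
        per_class_precision=prec,
        per_class_recall=rec,
        per_class_f1=f1,
        n_per_class=support.astype(int),
    )


def stratified_group_folds(
    labels: np.ndarray,
    groups: np.ndarray | None,
    k: int,
    seed: int,
) -> list[np.ndarray]:
    """Group-aware stratified k-fold partition (greedy deficit assignment)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"cannot stratify: k={k} exceeds smallest class count {counts.min()}"
        )
    if groups is None:
        groups = np.arange(len(labels)).astype(str)
    rng = np.random.default_rng(seed)
    fractions = np.full(k, 1.0 / k)
    return _greedy_group_assign(labels, np.asarray(groups), fractions, True, rng)


def cross_validate(
    fm: FeatureMatrix,
    fit_predict,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Group-aware stratified k-fold CV of a full pipeline.

    ``fit_predict(train_fm, eval_fm) -> int predictions`` is refit from
    scratch inside every fold. Returns per-fold reports plus mean +- SD
    aggregates for BAC / precision / recall / F1.
    """
    classes = np.unique(fm.labels)
    enc = {c: i for i, c in enumerate(classes)}
    y = np.array([enc[l] for l in fm.labels])
    folds = stratified_group_folds(fm.labels, fm.groups, k, seed)
    reports: list[MetricsReport] = []
    for fold_idx in folds:
        mask = np.ones(fm.n, dtype=bool)
        mask[fold_idx] = False
        train_fm = fm.subset_rows(np.flatnonzero(mask))
        eval_fm = fm.subset_rows(fold_idx)
        pred = np.asarray(fit_predict(train_fm, eval_fm))
        reports.append(metrics_report(y[fold_idx], pred, len(classes)))
    agg = {}
    for name in ("bac", "precision", "recall", "f1"):
        vals = np.array([getattr(r, name) for r in reports])
        agg[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return {"folds": reports, "aggregate": agg, "fold_indices": folds}


def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Classic paired t on per-fold metric differences; two-sided p, df=k-1."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * sstats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def fisher_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Trace(between-class scatter) / trace(within-class scatter)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    mu = X.mean(axis=0)
    sb = 0.0
    sw = 0.0
    for c in np.unique(labels):
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        sb += len(Xc) * float(((mc - mu) ** 2).sum())
        sw += float(((Xc - mc) ** 2).sum())
    if sw == 0:
        return np.inf
    return sb / sw


def separability_report(
    X_before: np.ndarray,
    X_after: np.ndarray,
    labels: np.ndarray,
    embed: bool = False,
    seed: int = 0,
) -> dict:
    """Class-separability indices before/after feature optimization.

    Fisher discriminant ratio and mean silhouette on both matrices; an
    optional 2-D t-SNE embedding of ``X_after`` is a visualization artifact
    only, never asserted on.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("separability requires >= 2 classes")
    out = {
        "fisher_ratio_before": fisher_ratio(X_before, labels),
        "fisher_ratio_after": fisher_ratio(X_after, labels),
    }
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < 2:
        warnings.warn("singleton class: silhouette undefined, omitted")
    else:
        from sklearn.metrics import silhouette_score

        out["silhouette_before"] = float(silhouette_score(X_before, labels))
        out["silhouette_after"] = float(silhouette_score(X_after, labels))
    if embed:
        from sklearn.manifold import TSNE

        n = len(labels)
        emb = TSNE(
            n_components=2, random_state=seed, perplexity=min(30.0, max(2.0, n / 4))
        ).fit_transform(np.asarray(X_after))
        out["embedding"] = emb
    return out
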