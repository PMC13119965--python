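"""End-to-end orchestration: config, stage seeding, ablation variants.

The pipeline runs preprocess -> CNN feature extraction -> per-branch
self-supervised refinement (training split only) -> fusion -> mRMR selection
(fit on train, applied to every split) -> per-split cosine top-K graphs ->
graph-attention training with early stopping -> test-set metrics. Ablation
variants reuse the same stages: ``plain`` feeds raw features straight to the
classifier; ``simclr`` / ``byol`` / ``deepcluster`` use a single refinement
branch; ``fused`` concatenates all three without selection; ``fused_mrmr``
is the full method.

A single global seed determines every stage seed by stable hashing of the
stage name, so reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .datatypes import FeatureMatrix, LabeledImageSet
from .evaluation import (
    MetricsReport,
    SplitSpec,
    metrics_report,
    split,
    stratified_group_folds,
)
from .extractor import ExtractorConfig, build_extractor, extract_features, preprocess, train_extractor
from .fusion_selection import SelectionConfig, apply_selection, fuse, mrmr_rank
from .graph import GraphConfig, build_graph
from .ssl_refiners import RefinerBundle, SSLConfig, refine, train_simclr, train_byol, train_deepcluster
from .vgcn import (
    DEFAULT_K_GRID,
    DEFAULT_LR_GRID,
    VGCNConfig,
    build_vgcn,
    grid_search,
    predict,
    train_vgcn,
)

__all__ = ["PipelineConfig", "VARIANTS", "stage_seed", "run_feature_variant", "run_all"]

log = logging.getLogger("histofuse")

# variant -> (refinement branches used, apply mRMR selection)
VARIANTS: dict[str, tuple[tuple[str, ...], bool]] = {
    "plain": ((), False),
    "simclr": (("simclr",), False),
    "deepcluster": (("deepcluster",), False),
    "byol": (("byol",), False),
    "fused": (("simclr", "deepcluster", "byol"), False),
    "fused_mrmr": (("simclr", "deepcluster", "byol"), True),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    toy_scale: bool = False
    variant: str = "fused_mrmr"
    cv_folds: int = 5
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    ssl: SSLConfig = field(default_factory=SSLConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    vgcn: VGCNConfig = field(default_factory=VGCNConfig)
    split: SplitSpec = field(default_factory=SplitSpec)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}"
            )
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")

    # ---- YAML round trip ----------------------------------------------------
    _SECTIONS = {
        "extractor": ExtractorConfig,
        "ssl": SSLConfig,
        "selection": SelectionConfig,
        "graph": GraphConfig,
        "vgcn": VGCNConfig,
        "split": SplitSpec,
    }

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, tuple):
                return [clean(o) for o in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return clean(dataclasses.asdict(self))

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _build_section(section_cls, data.pop(name))
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(os.fspath(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def toy(self) -> "PipelineConfig":
        """Desk-scale profile: halved CNN, fewer epochs, small grids."""
        return replace(
            self,
            toy_scale=True,
            extractor=ExtractorConfig.toy(
                n_classes=self.extractor.n_classes, seed=self.extractor.seed
            ),
            ssl=replace(self.ssl, epochs=min(self.ssl.epochs, 30)),
            vgcn=replace(self.vgcn, epochs=min(self.vgcn.epochs, 60)),
            lr_grid=(1e-3, 3e-3),
            k_grid=(5, 15),
        )


def _build_section(section_cls, data):
    if not isinstance(data, dict):
        raise ValueError(f"config section for {section_cls.__name__} must be a mapping")
    valid = {f.name: f for f in dataclasses.fields(section_cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in {section_cls.__name__} section"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return section_cls(**coerced)


def _encode_labels(*fms: FeatureMatrix) -> tuple[list, list[np.ndarray]]:
    classes = sorted({str(l) for fm in fms for l in fm.labels})
    enc = {c: i for i, c in enumerate(classes)}
    return classes, [np.array([enc[str(l)] for l in fm.labels]) for fm in fms]


def _train_branch(branch: str, X_train: FeatureMatrix, cfg: SSLConfig) -> RefinerBundle:
    bundle = RefinerBundle(config=cfg)
    if branch == "simclr":
        bundle.simclr, bundle.simclr_history = train_simclr(X_train, cfg)
    elif branch == "byol":
        bundle.byol = train_byol(X_train, cfg)
    else:
        bundle.deepcluster = train_deepcluster(X_train, cfg)
    return bundle


def run_feature_variant(
    train_fm: FeatureMatrix,
    val_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    cfg: PipelineConfig,
    do_grid_search: bool = False,
) -> dict:
    """Run the post-extraction pipeline on pre-split feature matrices."""
    branches, use_mrmr = VARIANTS[cfg.variant]
    classes, (y_train, y_val, y_test) = _encode_labels(train_fm, val_fm, test_fm)
    splits = {"train": train_fm, "val": val_fm, "test": test_fm}
    out: dict = {"classes": classes, "variant": cfg.variant}

    if branches:
        ssl_cfg = replace(
            cfg.ssl, input_dim=train_fm.d, seed=stage_seed(cfg.seed, "ssl")
        )
        ordered = [b for b in cfg.selection.branch_order if b in branches]
        bundles = {}
        for b in ordered:
            t0 = time.time()
            bundles[b] = _train_branch(b, train_fm, ssl_cfg)
            log.info("trained %s head in %.1fs", b, time.time() - t0)
        refined = {
            name: [refine(bundles[b], b, fm) for b in ordered]
            for name, fm in splits.items()
        }
        fused = {
            name: fuse(mats, ordered) if len(mats) > 1 else mats[0]
            for name, mats in refined.items()
        }
        out["bundles"] = bundles
    else:
        fused = dict(splits)

    if use_mrmr:
        sel_cfg = cfg.selection
        if sel_cfg.n_select > fused["train"].d:
            sel_cfg = replace(sel_cfg, n_select=fused["train"].d)
        selection = mrmr_rank(fused["train"], sel_cfg, labels=y_train)
        selected = {name: apply_selection(fm, selection) for name, fm in fused.items()}
        out["selection"] = selection
    else:
        selected = fused

    out["features"] = selected
    width = selected["train"].d
    vgcn_cfg = replace(
        cfg.vgcn,
        in_dim=width,
        n_classes=len(classes),
        seed=stage_seed(cfg.seed, "vgcn"),
    )

    if do_grid_search:
        (best_lr, best_k), table = grid_search(
            selected["train"],
            selected["val"],
            y_train,
            y_val,
            vgcn_cfg,
            cfg.graph,
            cfg.lr_grid,
            cfg.k_grid,
        )
        vgcn_cfg = replace(vgcn_cfg, learning_rate=best_lr)
        graph_cfg = replace(cfg.graph, top_k=best_k)
        out["grid_table"] = table
        out["grid_best"] = (best_lr, best_k)
        log.info("grid search best: lr=%g top_k=%d", best_lr, best_k)
    else:
        graph_cfg = cfg.graph

    graphs = {
        "train": build_graph(selected["train"], y_train, graph_cfg),
        "val": build_graph(selected["val"], None, graph_cfg),
        "test": build_graph(selected["test"], None, graph_cfg),
    }
    model = build_vgcn(vgcn_cfg)
    train_vgcn(model, graphs["train"], graphs["val"], val_labels=y_val)
    pred, probs = predict(model, graphs["test"])
    out.update(
        {
            "graphs": graphs,
            "model": model,
            "test_pred": pred,
            "test_probs": probs,
            "metrics": metrics_report(y_test, pred, len(classes)),
            "y": {"train": y_train, "val": y_val, "test": y_test},
        }
    )
    return out


def extract_split_features(
    images: LabeledImageSet, cfg: PipelineConfig
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Preprocess, split at the patient level, train the CNN and extract
    per-split 128-d feature matrices."""
    pre = preprocess(images, cfg.extractor.input_side)
    spec = replace(cfg.split, seed=stage_seed(cfg.seed, "split"))
    tr, va, te = split(pre.labels, pre.groups, spec)
    ext_cfg = replace(
        cfg.extractor,
        n_classes=len(pre.class_names),
        seed=stage_seed(cfg.seed, "extractor"),
    )
    extractor = build_extractor(ext_cfg)
    t0 = time.time()
    train_extractor(extractor, pre.subset(tr), pre.subset(va), ext_cfg)
    log.info("trained CNN extractor in %.1fs", time.time() - t0)
    fms = []
    for idx in (tr, va, te):
        sub = pre.subset(idx)
        fm = extract_features(extractor, sub)
        # carry original class names, not integer codes
        fm.labels = np.array([pre.class_names[int(l)] for l in sub.labels])
        fms.append(fm)
    return tuple(fms)


def split_features(fm: FeatureMatrix, cfg: PipelineConfig):
    spec = replace(cfg.split, seed=stage_seed(cfg.seed, "split"))
    tr, va, te = split(fm.labels, fm.groups, spec)
    return fm.subset_rows(tr), fm.subset_rows(va), fm.subset_rows(te)


def run_all(
    cfg: PipelineConfig,
    input_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    do_grid_search: bool = False,
) -> dict:
    """Full pipeline from an image directory or feature CSV to a run
    directory with features, selections, graphs, model history and metrics."""
    os.makedirs(out_dir, exist_ok=True)
    input_path = os.fspath(input_path)
    cfg_for_run = cfg.toy() if cfg.toy_scale else cfg
    stage = "input"
    try:
        if os.path.isdir(input_path):
            stage = "extract"
            images = LabeledImageSet.load(input_path)
            train_fm, val_fm, test_fm = extract_split_features(images, cfg_for_run)
        else:
            stage = "split"
            fm = FeatureMatrix.from_csv(input_path)
            train_fm, val_fm, test_fm = split_features(fm, cfg_for_run)
        for name, fm_ in (("train", train_fm), ("val", val_fm), ("test", test_fm)):
            fm_.to_csv(os.path.join(out_dir, f"features_{name}.csv"))
        stage = cfg_for_run.variant
        result = run_feature_variant(
            train_fm, val_fm, test_fm, cfg_for_run, do_grid_search
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, fm_ in result["features"].items():
        fm_.to_csv(os.path.join(out_dir, f"selected_{name}.csv"))
    if "selection" in result:
        result["selection"].to_json(os.path.join(out_dir, "selection.json"))
    for name, g in result["graphs"].items():
        g.save(
            os.path.join(out_dir, f"graph_{name}_edges.tsv"),
            os.path.join(out_dir, f"graph_{name}_nodes.csv"),
        )
    if "grid_table" in result:
        result["grid_table"].to_csv(os.path.join(out_dir, "grid_search.csv"))
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(result["metrics"].to_dict(), fh, indent=2)
    with open(os.path.join(out_dir, "history.json"), "w") as fh:
        json.dump(result["model"].history, fh, indent=2)
    cfg_for_run.to_yaml(os.path.join(out_dir, "config.yaml"))
    log.info("run complete: test BAC %.4f", result["metrics"].bac)
    return result


def cross_validate_variant(
    fm: FeatureMatrix, cfg: PipelineConfig, k: int | None = None
) -> dict:
    """Group-aware stratified k-fold CV of the configured variant.

    Each fold refits the full post-extraction pipeline from scratch; within
    a fold the non-test pool is re-split 82/18 for early stopping.
    """
    k = k or cfg.cv_folds
    folds = stratified_group_folds(
        fm.labels, fm.groups, k, stage_seed(cfg.seed, "cv")
    )
    classes = sorted({str(l) for l in fm.labels})
    enc = {c: i for i, c in enumerate(classes)}
    reports: list[MetricsReport] = []
    for i, fold_idx in enumerate(folds):
        mask = np.ones(fm.n, dtype=bool)
        mask[fold_idx] = False
        pool = fm.subset_rows(np.flatnonzero(mask))
        inner = SplitSpec(
            fractions=(0.82, 0.18, 0.0 + 1e-12),
            seed=stage_seed(cfg.seed, f"cv_inner{i}"),
        )
        # three-way split with a vanishing test share: use first two parts
        tr, va, _ = split(pool.labels, pool.groups, inner)
        res = run_feature_variant(
            pool.subset_rows(tr), pool.subset_rows(va), fm.subset_rows(fold_idx), cfg
        )
        y_true = np.array([enc[str(l)] for l in fm.subset_rows(fold_idx).labels])
        reports.append(metrics_report(y_true, res["test_pred"], len(classes)))
    agg = {
        name: {
            "mean": float(np.mean([getattr(r, name) for r in reports])),
            "sd": float(np.std([getattr(r, name) for r in reports], ddof=1)),
        }
        for name in ("bac", "precision", "recall", "f1")
    }
    return {"folds": reports, "aggregate": agg, "fold_indices": folds}
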