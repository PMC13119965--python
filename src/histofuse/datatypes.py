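"""Core data containers passed between pipeline stages.

``LabeledImageSet`` holds RGB images with class labels and optional patient
groups; ``FeatureMatrix`` is the n-samples x d-features currency every stage
after the extractor consumes and produces. Both round-trip through plain-text
formats (PNG trees with a manifest CSV, and CSV tables).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class LabeledImageSet:
    """Images + class labels + optional patient groups.

    images: list of (H, W, 3) float arrays in [0, 1] (sizes may vary before
    preprocessing). labels: per-image class names (str) or encoded ints.
    groups: per-image patient/slide identifier, or None.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    groups: np.ndarray | None = None
    class_names: list[str] | None = None
    label_map: dict[str, int] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if self.groups is not None and len(self.groups) != len(self.labels):
            raise ValueError("groups and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            groups=None if self.groups is None else self.groups[idx],
            class_names=self.class_names,
            label_map=self.label_map,
        )

    def save(self, root: str | os.PathLike) -> None:
        """Write ``<root>/<class>/<id>.png`` plus ``manifest.csv``."""
        root = os.fspath(root)
        rows = []
        counters: dict[str, int] = {}
        for i, (img, lab) in enumerate(zip(self.images, self.labels)):
            lab = str(lab)
            cdir = os.path.join(root, lab)
            os.makedirs(cdir, exist_ok=True)
            counters[lab] = counters.get(lab, 0)
            fname = os.path.join(lab, f"{counters[lab]:05d}.png")
            counters[lab] += 1
            arr = np.clip(np.asarray(img) * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(os.path.join(root, fname))
            rows.append(
                {
                    "file": fname,
                    "label": lab,
                    "patient_id": "" if self.groups is None else str(self.groups[i]),
                }
            )
        pd.DataFrame(rows).to_csv(os.path.join(root, "manifest.csv"), index=False)

    @classmethod
    def load(cls, root: str | os.PathLike) -> "LabeledImageSet":
        """Read an image tree; uses ``manifest.csv`` when present, else the
        ``<root>/<class>/*.png`` layout with no patient groups."""
        root = os.fspath(root)
        manifest = os.path.join(root, "manifest.csv")
        images, labels, groups = [], [], []
        if os.path.exists(manifest):
            df = pd.read_csv(manifest, keep_default_na=False)
            for _, row in df.iterrows():
                path = os.path.join(root, row["file"])
                images.append(_read_rgb(path))
                labels.append(str(row["label"]))
                groups.append(str(row.get("patient_id", "")) or None)
            has_groups = all(g is not None for g in groups)
            return cls(
                images,
                np.array(labels),
                np.array(groups) if has_groups else None,
                class_names=sorted(set(labels)),
            )
        for cname in sorted(os.listdir(root)):
            cdir = os.path.join(root, cname)
            if not os.path.isdir(cdir):
                continue
            for fname in sorted(os.listdir(cdir)):
                if fname.lower().endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff")):
                    images.append(_read_rgb(os.path.join(cdir, fname)))
                    labels.append(cname)
        if not images:
            raise FileNotFoundError(f"no images found under {root!r}")
        return cls(images, np.array(labels), None, class_names=sorted(set(labels)))


def _read_rgb(path: str) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                im = im.convert("RGB")
            return np.asarray(im, dtype=np.float64) / 255.0
    except OSError as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc


@dataclass
class FeatureMatrix:
    """n x d numeric features with aligned labels and optional groups."""

    X: np.ndarray
    labels: np.ndarray
    groups: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match number of rows")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != self.X.shape[0]:
                raise ValueError("groups length must match number of rows")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.X[idx],
            self.labels[idx],
            None if self.groups is None else self.groups[idx],
            list(self.feature_names),
        )

    def subset_cols(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.X[:, idx],
            self.labels,
            self.groups,
            [self.feature_names[i] for i in idx],
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        if self.groups is not None:
            df["group"] = self.groups
        df.to_csv(os.fspath(path), index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        df = pd.read_csv(os.fspath(path))
        if "label" not in df.columns:
            raise ValueError(f"{path!r} has no 'label' column")
        groups = df.pop("group").to_numpy() if "group" in df.columns else None
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=np.float64), labels, groups, list(df.columns))
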