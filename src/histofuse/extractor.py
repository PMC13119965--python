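"""Custom CNN feature extractor for histopathology-style tiles.

The network follows a fixed funnel: three 3x3 convolutions with 32 filters
(each + batch-norm + ReLU) and a halving max-pool, two 3x3 convolutions with
64 filters and another halving pool (224 -> 112 -> 56 spatially at the
default input side), then one further 128-filter convolution block with a
pool, global average pooling, a 128-unit dense feature layer (ReLU) and a
softmax classification head. Features are read from the 128-unit penultimate
layer, post-activation, so every image maps to a 128-dimensional vector.

A halved-width toy profile (side 64) keeps training tractable on one CPU.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from . import _nn
from ._autodiff import DTYPE, Tensor
from .datatypes import FeatureMatrix, LabeledImageSet

__all__ = [
    "ExtractorConfig",
    "TrainedExtractor",
    "preprocess",
    "build_extractor",
    "train_extractor",
    "extract_features",
]


@dataclass(frozen=True)
class ExtractorConfig:
    input_side: int = 224
    block1_widths: tuple[int, ...] = (32, 32, 32)
    block2_widths: tuple[int, ...] = (64, 64)
    tail_width: int = 128
    feature_dim: int = 128
    n_classes: int = 3
    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim < 1:
            raise ValueError(f"feature_dim must be >= 1, got {self.feature_dim}")
        for widths in (self.block1_widths, self.block2_widths):
            if any(w < 1 for w in widths):
                raise ValueError(f"conv widths must be positive, got {widths}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.input_side % 8 != 0:
            raise ValueError(f"input_side must be divisible by 8, got {self.input_side}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")

    @classmethod
    def toy(cls, n_classes: int = 3, seed: int = 0, epochs: int = 30) -> "ExtractorConfig":
        """Halved-width profile at side 64 for desk-scale training."""
        return cls(
            input_side=64,
            block1_widths=(16, 16, 16),
            block2_widths=(32, 32),
            tail_width=64,
            n_classes=n_classes,
            epochs=epochs,
            seed=seed,
        )


class _CNN(_nn.Module):
    def __init__(self, cfg: ExtractorConfig, rng: np.random.Generator):
        self.convs1 = []
        in_ch = 3
        for w in cfg.block1_widths:
            self.convs1.append((_nn.Conv2d(in_ch, w, rng), _nn.BatchNorm2d(w)))
            in_ch = w
        self.convs2 = []
        for w in cfg.block2_widths:
            self.convs2.append((_nn.Conv2d(in_ch, w, rng), _nn.BatchNorm2d(w)))
            in_ch = w
        self.tail_conv = _nn.Conv2d(in_ch, cfg.tail_width, rng)
        self.tail_bn = _nn.BatchNorm2d(cfg.tail_width)
        self.fc_feat = _nn.Dense(cfg.tail_width, cfg.feature_dim, rng)
        self.fc_out = _nn.Dense(cfg.feature_dim, cfg.n_classes, rng)

    def parameters(self):
        params = []
        for conv, bn in self.convs1 + self.convs2:
            params.extend(conv.parameters() + bn.parameters())
        params.extend(self.tail_conv.parameters() + self.tail_bn.parameters())
        params.extend(self.fc_feat.parameters() + self.fc_out.parameters())
        return params

    def forward(self, x: Tensor, training: bool) -> tuple[Tensor, Tensor]:
        """Returns (features (n, feature_dim), logits (n, n_classes))."""
        h = x
        for conv, bn in self.convs1:
            h = bn(conv(h), training).relu()
        h = h.maxpool2x2()
        for conv, bn in self.convs2:
            h = bn(conv(h), training).relu()
        h = h.maxpool2x2()
        h = self.tail_bn(self.tail_conv(h), training).relu()
        h = h.maxpool2x2()
        h = h.mean(axis=(2, 3))  # global average pool -> (n, tail_width)
        feats = self.fc_feat(h).relu()
        return feats, self.fc_out(feats)


@dataclass
class TrainedExtractor:
    config: ExtractorConfig
    model: _CNN
    label_map: dict[str, int] | None = None
    history: list[dict] = field(default_factory=list)
    trained: bool = False

    def describe(self) -> dict:
        s = self.config.input_side
        return {
            "input": [s, s, 3],
            "block1": list(self.config.block1_widths),
            "after_pool1": [s // 2, s // 2, self.config.block1_widths[-1]],
            "block2": list(self.config.block2_widths),
            "after_pool2": [s // 4, s // 4, self.config.block2_widths[-1]],
            "tail_conv": self.config.tail_width,
            "feature_dim": self.config.feature_dim,
            "n_classes": self.config.n_classes,
        }

    def save(self, checkpoint_path: str | os.PathLike, sidecar_path: str | os.PathLike) -> None:
        np.savez(
            os.fspath(checkpoint_path),
            **{f"p{i}": p.data for i, p in enumerate(self.model.parameters())},
        )
        with open(os.fspath(sidecar_path), "w") as fh:
            json.dump(
                {
                    "architecture": self.describe(),
                    "config": asdict(self.config),
                    "label_map": self.label_map,
                    "trained": self.trained,
                },
                fh,
                indent=2,
            )


def preprocess(images: LabeledImageSet, side: int) -> LabeledImageSet:
    """Resize to side x side, clamp to [0,1], integer-encode labels.

    The label <-> index map (sorted class names) is stored on the returned
    set; original string labels remain recoverable through it.
    """
    out_images = []
    for i, img in enumerate(images.images):
        img = np.asarray(img, dtype=float)
        if img.ndim != 3 or img.shape[2] != 3:
            raise OSError(f"image {i} is not RGB (shape {img.shape})")
        if img.shape[0] != side or img.shape[1] != side:
            img = resize(img, (side, side), anti_aliasing=True, preserve_range=True)
        out_images.append(np.clip(img, 0.0, 1.0))
    class_names = sorted({str(l) for l in images.labels})
    label_map = {c: i for i, c in enumerate(class_names)}
    encoded = np.array([label_map[str(l)] for l in images.labels])
    return LabeledImageSet(
        out_images,
        encoded,
        images.groups,
        class_names=class_names,
        label_map=label_map,
    )


def build_extractor(cfg: ExtractorConfig) -> TrainedExtractor:
    """Initialize the network (untrained) from the config seed."""
    rng = np.random.default_rng(cfg.seed)
    return TrainedExtractor(config=cfg, model=_CNN(cfg, rng))


def _to_batch(images: list[np.ndarray], side: int) -> np.ndarray:
    arr = np.stack(images).astype(DTYPE)
    if arr.shape[1] != side or arr.shape[2] != side:
        raise ValueError(
            f"image side {arr.shape[1]}x{arr.shape[2]} does not match expected {side}"
        )
    return arr.transpose(0, 3, 1, 2)  # (n, 3, side, side)


def train_extractor(
    extractor: TrainedExtractor,
    train: LabeledImageSet,
    val: LabeledImageSet,
    cfg: ExtractorConfig | None = None,
) -> TrainedExtractor:
    """Adam + cross-entropy training with per-epoch train/val history."""
    cfg = cfg or extractor.config
    y_train = np.asarray(train.labels, dtype=int)
    y_val = np.asarray(val.labels, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    X_train = _to_batch(train.images, cfg.input_side)
    X_val = _to_batch(val.images, cfg.input_side)
    model = extractor.model
    extractor.label_map = train.label_map
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _nn.Adam(model.parameters(), cfg.learning_rate)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y_train))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, logits = model.forward(Tensor(X_train[idx]), training=True)
            loss = _nn.cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        _, val_logits = model.forward(Tensor(X_val), training=False)
        val_loss = float(_nn.cross_entropy(val_logits, y_val).data)
        val_acc = float((val_logits.data.argmax(axis=1) == y_val).mean())
        extractor.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": correct / len(y_train),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
    extractor.trained = cfg.epochs > 0
    return extractor


def extract_features(
    extractor: TrainedExtractor,
    images: LabeledImageSet,
    allow_untrained: bool = False,
    batch_size: int = 32,
) -> FeatureMatrix:
    """Inference-mode features, one row per image in input order."""
    if not extractor.trained and not allow_untrained:
        raise ValueError("extractor is untrained; pass allow_untrained=True to force")
    cfg = extractor.config
    names = [f"cnn{i}" for i in range(cfg.feature_dim)]
    if len(images) == 0:
        return FeatureMatrix(
            np.empty((0, cfg.feature_dim)), images.labels, images.groups, names
        )
    X = _to_batch(images.images, cfg.input_side)
    rows = []
    for start in range(0, len(X), batch_size):
        feats, _ = extractor.model.forward(
            Tensor(X[start : start + batch_size]), training=False
        )
        rows.append(np.asarray(feats.data, dtype=float))
    return FeatureMatrix(np.concatenate(rows), images.labels, images.groups, names)
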