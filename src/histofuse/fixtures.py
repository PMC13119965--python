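"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators: ``gen_images`` paints H&E-like tiles — a pink-tinted stromal
background with darker purple elliptical "nuclei" whose density, elongation
and tint differ by class — and ``gen_features`` draws Gaussian-mixture
feature tables with informative, redundant (affine copies + noise) and pure
noise columns. Both are fully determined by their spec + seed, so tests and
the acceptance pipeline never need external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FeatureMatrix, LabeledImageSet

__all__ = [
    "TextureParams",
    "SyntheticImageSpec",
    "SyntheticFeatureSpec",
    "gen_images",
    "gen_features",
]


@dataclass(frozen=True)
class TextureParams:
    """Per-class texture controls.

    blob_density: target fraction of tile area covered by nuclei (0-1).
    eccentricity: nucleus elongation in [0, 1); 0 gives circles.
    tint: RGB multiplier in [0,1]^3 blended into the background stain.
    """

    blob_density: float = 0.05
    eccentricity: float = 0.3
    tint: tuple[float, float, float] = (1.0, 0.85, 0.95)

    def __post_init__(self):
        if not 0.0 <= self.blob_density <= 1.0:
            raise ValueError(f"blob_density must be in [0,1], got {self.blob_density}")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError(f"eccentricity must be in [0,1), got {self.eccentricity}")
        if len(self.tint) != 3 or any(not 0.0 <= t <= 1.0 for t in self.tint):
            raise ValueError(f"tint components must be in [0,1], got {self.tint}")


_DEFAULT_TEXTURES = (
    TextureParams(0.04, 0.15, (1.0, 0.82, 0.92)),
    TextureParams(0.10, 0.55, (0.95, 0.72, 0.98)),
    TextureParams(0.17, 0.35, (0.88, 0.80, 0.86)),
)


@dataclass(frozen=True)
class SyntheticImageSpec:
    n_per_class: int = 10
    classes: tuple[str, ...] = ("Normal", "ACC", "SCC")
    side: int = 224
    seed: int = 0
    texture_params: tuple[TextureParams, ...] | None = None
    images_per_patient: int = 5

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.side < 32:
            raise ValueError(f"side must be >= 32, got {self.side}")
        if len(self.classes) < 1:
            raise ValueError("classes must be nonempty")
        if self.images_per_patient < 1:
            raise ValueError(
                f"images_per_patient must be >= 1, got {self.images_per_patient}"
            )
        if self.texture_params is not None and len(self.texture_params) != len(
            self.classes
        ):
            raise ValueError("texture_params must have one entry per class")

    def resolved_textures(self) -> tuple[TextureParams, ...]:
        if self.texture_params is not None:
            return tuple(self.texture_params)
        reps = -(-len(self.classes) // len(_DEFAULT_TEXTURES))
        return (_DEFAULT_TEXTURES * reps)[: len(self.classes)]


_BACKGROUND = np.array([0.93, 0.80, 0.88])  # eosin-pink stroma
_NUCLEUS = np.array([0.38, 0.22, 0.52])  # hematoxylin-purple nuclei


def _paint_tile(rng: np.random.Generator, side: int, tp: TextureParams) -> np.ndarray:
    tint = np.asarray(tp.tint)
    img = np.empty((side, side, 3))
    img[:] = _BACKGROUND * tint
    img += rng.normal(0.0, 0.02, size=(side, side, 3))

    r0 = max(2.0, side / 24.0)  # mean nucleus radius, pixels
    blob_area = np.pi * r0 * r0
    n_blobs = int(round(tp.blob_density * side * side / blob_area))
    aspect = 1.0 / np.sqrt(1.0 - tp.eccentricity**2)
    a_ax = r0 * np.sqrt(aspect)  # semi-major
    b_ax = r0 / np.sqrt(aspect)  # semi-minor; area preserved

    yy, xx = np.mgrid[0:side, 0:side]
    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * a_ax + 2.0  # rejection radius: no touching ellipses
    attempts = 0
    while len(centers) < n_blobs and attempts < 60 * max(n_blobs, 1):
        attempts += 1
        cy = rng.uniform(a_ax, side - a_ax)
        cx = rng.uniform(a_ax, side - a_ax)
        if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep**2 for py, px in centers):
            centers.append((cy, cx))
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0
            shade = rng.uniform(0.85, 1.1)
            img[mask] = _NUCLEUS * shade
    return np.clip(img, 0.0, 1.0)


def gen_images(spec: SyntheticImageSpec) -> LabeledImageSet:
    """Generate ``n_per_class x |classes|`` synthetic H&E-like tiles.

    Patient groups are attached: ``images_per_patient`` consecutive images of
    a class share one synthetic patient; patients never straddle classes.
    """
    rng = np.random.default_rng(spec.seed)
    textures = spec.resolved_textures()
    images, labels, groups = [], [], []
    for ci, cname in enumerate(spec.classes):
        for i in range(spec.n_per_class):
            images.append(_paint_tile(rng, spec.side, textures[ci]))
            labels.append(cname)
            groups.append(f"{cname}_p{i // spec.images_per_patient:03d}")
    return LabeledImageSet(
        images,
        np.array(labels),
        np.array(groups),
        class_names=list(spec.classes),
    )


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Gaussian-mixture feature table.

    Informative columns get class-conditional means drawn so the expected
    pairwise class separation per column is ``class_sep`` within-class SDs
    (within-class SD fixed at 1). Redundant columns are affine images of
    informative columns plus N(0, redundancy_noise_sd^2) noise. Noise columns
    are N(0,1) independent of the label.
    """

    n_per_class: int = 50
    n_classes: int = 3
    d_informative: int = 5
    d_redundant: int = 0
    d_noise: int = 5
    class_sep: float = 3.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0
    samples_per_group: int = 5

    def __post_init__(self):
        for name in ("n_per_class", "n_classes", "samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("d_informative", "d_redundant", "d_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.d_informative + self.d_redundant + self.d_noise < 1:
            raise ValueError("total dimension must be >= 1")
        if self.d_redundant > 0 and self.d_informative == 0:
            raise ValueError("d_redundant > 0 requires d_informative >= 1")
        if self.class_sep < 0:
            raise ValueError(f"class_sep must be >= 0, got {self.class_sep}")
        if self.redundancy_noise_sd < 0:
            raise ValueError(
                f"redundancy_noise_sd must be >= 0, got {self.redundancy_noise_sd}"
            )

    @property
    def d_total(self) -> int:
        return self.d_informative + self.d_redundant + self.d_noise


def gen_features(spec: SyntheticFeatureSpec) -> FeatureMatrix:
    """Draw the mixture table; column order informative, redundant, noise.

    Feature names carry provenance: ``inf<j>``, ``red<j>_of_inf<k>``,
    ``noise<j>``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    labels = np.repeat([f"class{c}" for c in range(spec.n_classes)], spec.n_per_class)

    # class centroids: E[(mu_c - mu_c')^2] = class_sep^2 per informative dim
    centroids = rng.normal(
        0.0, spec.class_sep / np.sqrt(2.0), size=(spec.n_classes, spec.d_informative)
    )
    class_idx = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    X_inf = centroids[class_idx] + rng.normal(size=(n, spec.d_informative))

    names = [f"inf{j}" for j in range(spec.d_informative)]
    blocks = [X_inf]

    if spec.d_redundant:
        src = rng.integers(0, spec.d_informative, size=spec.d_redundant)
        slope = rng.uniform(0.5, 1.5, size=spec.d_redundant) * rng.choice(
            [-1.0, 1.0], size=spec.d_redundant
        )
        intercept = rng.normal(size=spec.d_redundant)
        X_red = (
            X_inf[:, src] * slope
            + intercept
            + rng.normal(0.0, spec.redundancy_noise_sd, size=(n, spec.d_redundant))
        )
        blocks.append(X_red)
        names += [f"red{j}_of_inf{src[j]}" for j in range(spec.d_redundant)]

    if spec.d_noise:
        blocks.append(rng.normal(size=(n, spec.d_noise)))
        names += [f"noise{j}" for j in range(spec.d_noise)]

    groups = np.array(
        [
            f"{labels[i]}_g{(i % spec.n_per_class) // spec.samples_per_group:03d}"
            for i in range(n)
        ]
    )
    return FeatureMatrix(np.concatenate(blocks, axis=1), labels, groups, names)
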