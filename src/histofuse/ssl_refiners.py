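"""Three self-supervised refinement heads over extracted feature vectors.

Each head maps d-dimensional CNN features to refined embeddings of the same
width, trained on the training split only with Gaussian-noise augmentation
(two views per sample):

* SimCLR — a two-layer projection encoder trained with the normalized
  temperature-scaled cross-entropy (NT-Xent) contrastive loss over cosine
  similarities; refined outputs are L2-normalized.
* BYOL — an online projector (+ linear predictor) regresses onto a target
  network updated only by an exponential moving average of the online
  weights; the loss is 2 - 2 cos between L2-normalized prediction and
  target, symmetrized over the two views.
* DeepCluster — alternates k-means pseudo-labeling of encoder outputs with
  cross-entropy training of the encoder + cluster head against those labels.

The bundle's ``refine`` contract is a deterministic inference-mode map.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._autodiff import DTYPE, Tensor
from .datatypes import FeatureMatrix

__all__ = [
    "SSLConfig",
    "RefinerBundle",
    "augment_noise",
    "nt_xent_loss",
    "byol_loss",
    "ema_update",
    "deepcluster_assign",
    "train_simclr",
    "train_byol",
    "train_deepcluster",
    "train_bundle",
    "refine",
]

BRANCHES = ("simclr", "byol", "deepcluster")


@dataclass(frozen=True)
class SSLConfig:
    input_dim: int = 128
    hidden_dim: int = 128
    output_dim: int = 128
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    noise_sd: float = 0.05
    seed: int = 0
    temperature: float = 0.5  # SimCLR
    ema_decay: float = 0.99  # BYOL
    n_clusters: int = 10  # DeepCluster

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ValueError(f"ema_decay must be in [0,1], got {self.ema_decay}")
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("input_dim", "hidden_dim", "output_dim", "epochs", "batch_size"):
            if getattr(self, name) < 0 or (name != "epochs" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")


# ---------------------------------------------------------------- augmentation
def augment_noise(X, sd: float, seed_or_rng=0):
    """Additive iid Gaussian(0, sd^2) perturbation; shape preserved."""
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(
            X.X + rng.normal(0.0, sd, size=X.X.shape) if sd > 0 else X.X.copy(),
            X.labels,
            X.groups,
            list(X.feature_names),
        )
    X = np.asarray(X, dtype=float)
    if sd == 0:
        return X.copy()
    return X + rng.normal(0.0, sd, size=X.shape)


# -------------------------------------------------------------------- losses
def nt_xent_loss(E, temperature: float) -> Tensor:
    """NT-Xent over 2N embeddings ordered as N positive pairs (2i, 2i+1).

    Rows are L2-normalized internally; for each anchor the positive is its
    partner and every other embedding in the batch is a negative. Per-anchor
    losses are averaged over the 2N anchors.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    E = E if isinstance(E, Tensor) else Tensor(np.asarray(E, dtype=DTYPE))
    two_n = E.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("embeddings must form N >= 1 positive pairs (2N rows)")
    Z = _nn.l2_normalize_rows(E)
    S = (Z @ Z.T) * DTYPE(1.0 / temperature)
    # exclude self-similarity from every anchor's denominator
    mask = Tensor(np.where(np.eye(two_n), -1e9, 0.0).astype(DTYPE))
    Sm = S + mask
    lse = Tensor(Sm.data.max(axis=1, keepdims=True))
    lse = ((Sm - lse).exp().sum(axis=1, keepdims=True).log() + lse).reshape(two_n)
    partner = np.arange(two_n) ^ 1
    pos = (S * Tensor(np.eye(two_n)[partner].astype(DTYPE))).sum(axis=1)
    return (lse - pos).mean()


def byol_loss(q, z_target) -> Tensor:
    """Mean over rows of ||q/||q|| - z/||z||||^2 = 2 - 2 cos(q, z)."""
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q, dtype=DTYPE))
    z = z_target if isinstance(z_target, Tensor) else Tensor(np.asarray(z_target, dtype=DTYPE))
    if q.ndim == 1:
        q = q.reshape(1, -1)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    if np.any(np.linalg.norm(q.data, axis=1) == 0) or np.any(
        np.linalg.norm(z.data, axis=1) == 0
    ):
        raise ValueError("byol_loss undefined for zero vectors")
    qn = _nn.l2_normalize_rows(q)
    zn = _nn.l2_normalize_rows(z)
    return ((qn - zn) ** 2).sum(axis=1).mean()


def ema_update(theta_online: list[np.ndarray], eps_target: list[np.ndarray], tau: float):
    """Elementwise target update eps <- tau*eps + (1-tau)*theta."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0,1], got {tau}")
    if len(theta_online) != len(eps_target):
        raise ValueError("parameter list length mismatch")
    out = []
    for th, ep in zip(theta_online, eps_target):
        if th.shape != ep.shape:
            raise ValueError(f"parameter shape mismatch: {th.shape} vs {ep.shape}")
        out.append((tau * ep + (1.0 - tau) * th).astype(ep.dtype))
    return out


# -------------------------------------------------------------------- k-means
def _kmeans(
    Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's algorithm with k-means++ seeding.

    Ties in assignment break to the lowest centroid index; an emptied cluster
    is re-seeded to the point farthest from its current centroid. Returns
    (assignments, centroids (k, d), per-iteration objective history).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < k:
        raise ValueError(f"k-means needs n >= k; got n={n}, k={k}")
    # k-means++ seeding
    centers = np.empty((k, Z.shape[1]))
    centers[0] = Z[rng.integers(n)]
    d2 = ((Z - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[c] = Z[rng.integers(n)]
        else:
            centers[c] = Z[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((Z - centers[c]) ** 2).sum(axis=1))

    history: list[float] = []
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = dist.argmin(axis=1)  # lowest index on ties
        history.append(float(dist[np.arange(n), new_assign].sum()))
        for c in range(k):
            members = new_assign == c
            if members.any():
                centers[c] = Z[members].mean(axis=0)
            else:  # re-seed to the globally farthest point
                far = int(dist[np.arange(n), new_assign].argmax())
                centers[c] = Z[far]
                new_assign[far] = c
        if np.array_equal(new_assign, assign) and len(history) > 1:
            break
        assign = new_assign
    return assign, centers, history


def deepcluster_assign(Z: np.ndarray, k: int, seed_or_rng=0):
    """K-means cluster assignment of encoded features.

    Returns (one-hot assignments Y of shape (n, k), centroid matrix C of
    shape (d, k) — one centroid per column).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    assign, centers, _ = _kmeans(Z, k, rng)
    Y = np.eye(k)[assign]
    return Y, centers.T


# ------------------------------------------------------------------- branches
class SimCLREncoder(_nn.Module):
    """Two affine maps with a rectifier between; outputs L2-normalized."""

    def __init__(self, cfg: SSLConfig, rng: np.random.Generator):
        self.fc1 = _nn.Dense(cfg.input_dim, cfg.hidden_dim, rng)
        self.fc2 = _nn.Dense(cfg.hidden_dim, cfg.output_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.l2_normalize_rows(self.fc2(self.fc1(x).relu()))


class BYOLNet(_nn.Module):
    """Affine -> batch-norm -> rectifier -> affine projector."""

    def __init__(self, cfg: SSLConfig, rng: np.random.Generator):
        self.fc1 = _nn.Dense(cfg.input_dim, cfg.hidden_dim, rng)
        self.bn = _nn.BatchNorm1d(cfg.hidden_dim)
        self.fc2 = _nn.Dense(cfg.hidden_dim, cfg.output_dim, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return self.fc2(self.bn(self.fc1(x), training).relu())


class DeepClusterEncoder(_nn.Module):
    """Affine -> rectifier -> affine encoder plus a linear cluster head."""

    def __init__(self, cfg: SSLConfig, rng: np.random.Generator):
        self.fc1 = _nn.Dense(cfg.input_dim, cfg.hidden_dim, rng)
        self.fc2 = _nn.Dense(cfg.hidden_dim, cfg.output_dim, rng)
        self.head = _nn.Dense(cfg.output_dim, cfg.n_clusters, rng)

    def encode(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def logits(self, x: Tensor) -> Tensor:
        return self.head(self.encode(x))


def _as_array(X) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


# -------------------------------------------------------------------- SimCLR
def train_simclr(X_train, cfg: SSLConfig):
    """Train the contrastive encoder; returns (encoder, loss history)."""
    X = _as_array(X_train)
    if X.shape[0] < 2:
        raise ValueError("SimCLR needs at least 2 training samples")
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"input width {X.shape[1]} != cfg.input_dim {cfg.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    enc = SimCLREncoder(cfg, rng)
    opt = _nn.Adam(enc.parameters(), cfg.learning_rate)
    history: list[float] = []
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(X.shape[0], cfg.batch_size, rng):
            if len(idx) < 2:
                continue
            xb = X[idx]
            v1 = augment_noise(xb, cfg.noise_sd, rng)
            v2 = augment_noise(xb, cfg.noise_sd, rng)
            # interleave so rows (2i, 2i+1) are the positive pair
            both = np.empty((2 * len(idx), X.shape[1]))
            both[0::2] = v1
            both[1::2] = v2
            z = enc(Tensor(both.astype(DTYPE), requires_grad=False))
            loss = nt_xent_loss(z, cfg.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)) if losses else 0.0)
    return enc, history


# ---------------------------------------------------------------------- BYOL
@dataclass
class BYOLBranch:
    online: BYOLNet
    predictor: _nn.Dense
    target: BYOLNet
    history: list[float] = field(default_factory=list)


def _copy_params(dst: _nn.Module, src: _nn.Module) -> None:
    for pd, ps in zip(dst.parameters(), src.parameters()):
        pd.data[...] = ps.data


def train_byol(X_train, cfg: SSLConfig) -> BYOLBranch:
    """Train the bootstrap branch; the target moves only by EMA."""
    X = _as_array(X_train)
    if X.shape[0] < 2:
        raise ValueError("BYOL needs at least 2 training samples")
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"input width {X.shape[1]} != cfg.input_dim {cfg.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    online = BYOLNet(cfg, rng)
    predictor = _nn.Dense(cfg.output_dim, cfg.output_dim, rng)
    target = BYOLNet(cfg, np.random.default_rng(cfg.seed + 1))
    _copy_params(target, online)
    branch = BYOLBranch(online, predictor, target)

    opt = _nn.Adam(online.parameters() + predictor.parameters(), cfg.learning_rate)
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(X.shape[0], cfg.batch_size, rng):
            xb = X[idx]
            v1 = Tensor(augment_noise(xb, cfg.noise_sd, rng).astype(DTYPE))
            v2 = Tensor(augment_noise(xb, cfg.noise_sd, rng).astype(DTYPE))
            # target runs with frozen (evaluation-mode) batch statistics
            t1 = target(v1, training=False).detach()
            t2 = target(v2, training=False).detach()
            loss = byol_loss(predictor(online(v1, training=True)), t2) + byol_loss(
                predictor(online(v2, training=True)), t1
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            new_target = ema_update(
                online.state_arrays(), target.state_arrays(), cfg.ema_decay
            )
            for p, arr in zip(target.parameters(), new_target):
                p.data[...] = arr
            target.bn.running_mean = online.bn.running_mean.copy()
            target.bn.running_var = online.bn.running_var.copy()
            losses.append(float(loss.data) / 2.0)
        branch.history.append(float(np.mean(losses)) if losses else 0.0)
    return branch


# ---------------------------------------------------------------- DeepCluster
@dataclass
class DeepClusterBranch:
    encoder: DeepClusterEncoder
    centroids: np.ndarray | None = None  # (d, k)
    history: list[dict] = field(default_factory=list)


def train_deepcluster(X_train, cfg: SSLConfig) -> DeepClusterBranch:
    """Alternate k-means pseudo-labeling and cross-entropy training."""
    X = _as_array(X_train)
    if X.shape[0] < cfg.n_clusters:
        raise ValueError(
            f"DeepCluster needs n >= n_clusters; got n={X.shape[0]}, k={cfg.n_clusters}"
        )
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"input width {X.shape[1]} != cfg.input_dim {cfg.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    enc = DeepClusterEncoder(cfg, rng)
    branch = DeepClusterBranch(enc)
    opt = _nn.Adam(enc.parameters(), cfg.learning_rate)
    for _ in range(cfg.epochs):
        Z = enc.encode(Tensor(X.astype(DTYPE))).data
        assign, centers, obj = _kmeans(Z, cfg.n_clusters, rng)
        branch.centroids = centers.T
        losses = []
        for idx in _batches(X.shape[0], cfg.batch_size, rng):
            xb = augment_noise(X[idx], cfg.noise_sd, rng)
            logits = enc.logits(Tensor(xb.astype(DTYPE)))
            loss = _nn.cross_entropy(logits, assign[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        branch.history.append(
            {"kmeans_objective": obj[-1], "ce_loss": float(np.mean(losses))}
        )
    return branch


# -------------------------------------------------------------------- bundle
@dataclass
class RefinerBundle:
    """The three trained refinement heads sharing a fit/refine contract."""

    config: SSLConfig
    simclr: SimCLREncoder | None = None
    simclr_history: list[float] = field(default_factory=list)
    byol: BYOLBranch | None = None
    deepcluster: DeepClusterBranch | None = None

    def trained(self, branch: str) -> bool:
        return getattr(self, branch) is not None


def train_bundle(X_train, cfg: SSLConfig) -> RefinerBundle:
    """Fit all three heads on the training split only."""
    bundle = RefinerBundle(config=cfg)
    bundle.simclr, bundle.simclr_history = train_simclr(X_train, cfg)
    bundle.byol = train_byol(X_train, cfg)
    bundle.deepcluster = train_deepcluster(X_train, cfg)
    return bundle


def refine(bundle: RefinerBundle, branch: str, X) -> FeatureMatrix:
    """Deterministic inference-mode refinement of any split's features."""
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}; expected one of {BRANCHES}")
    if not bundle.trained(branch):
        raise ValueError(f"branch {branch!r} is not trained")
    arr = _as_array(X)
    if arr.shape[1] != bundle.config.input_dim:
        raise ValueError(
            f"input width {arr.shape[1]} != trained width {bundle.config.input_dim}"
        )
    t = Tensor(arr.astype(DTYPE))
    if branch == "simclr":
        out = bundle.simclr(t).data
    elif branch == "byol":
        out = bundle.byol.online(t, training=False).data
    else:
        out = bundle.deepcluster.encoder.encode(t).data
    out = np.asarray(out, dtype=float)
    names = [f"{branch}_{i}" for i in range(out.shape[1])]
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(out, X.labels, X.groups, names)
    return FeatureMatrix(out, np.zeros(out.shape[0], dtype=int), None, names)
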