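"""Hierarchical point-cloud semantic segmentation (CAVF-PointNet++).

The backbone is the classic set-abstraction / feature-propagation design:
farthest point sampling picks representative centers, spherical ball
queries group neighborhoods at multiple radii (multi-scale grouping), a
small shared MLP with max-pooling encodes each group, and inverse-distance
interpolation with skip connections propagates coarse features back to
every point. Two additions target organ confusion and class imbalance:

- CAApoint: a context-anchor attention block inside each group encoder
  (global average pool -> 1x1 conv channel reduction -> horizontal and
  vertical depthwise convolutions -> 1x1 fusion conv -> sigmoid), whose
  weights multiply the encoded feature map;
- varifocal loss: an asymmetric focal-style objective
  ``VFL(p, q) = -q log p - (1 - q)^gamma log(1 - p)`` applied per class
  with sigmoid confidences.

Both are switchable; with attention off and cross-entropy on, the model
reduces exactly to plain PointNet++.

Everything runs on the package's own numpy autodiff engine, so training
is CPU-only and meant for reduced problem sizes; the architecture,
losses and contracts match the full-scale design.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin

from .autodiff import Adam, Tensor, concat
from .containers import LabeledCloud, PointCloud

DEFAULT_SA_CONFIG = [
    {
        "n_centers": 1024,
        "scales": [
            {"radius": 0.02, "n_samples": 16, "mlp": [32, 32, 64]},
            {"radius": 0.04, "n_samples": 32, "mlp": [32, 32, 64]},
        ],
    },
    {
        "n_centers": 256,
        "scales": [
            {"radius": 0.04, "n_samples": 16, "mlp": [64, 64, 128]},
            {"radius": 0.08, "n_samples": 32, "mlp": [64, 64, 128]},
        ],
    },
    {
        "n_centers": 64,
        "scales": [
            {"radius": 0.08, "n_samples": 16, "mlp": [128, 128, 256]},
            {"radius": 0.16, "n_samples": 32, "mlp": [128, 128, 256]},
        ],
    },
]
DEFAULT_FP_MLPS = [[128, 128], [256, 128], [256, 256]]

# reduced architecture for CPU-scale experiments (2 SA levels, width <= 64)
TOY_SA_CONFIG = [
    {
        "n_centers": 192,
        "scales": [
            {"radius": 0.10, "n_samples": 24, "mlp": [32, 64]},
            {"radius": 0.20, "n_samples": 32, "mlp": [32, 64]},
        ],
    },
    {
        "n_centers": 48,
        "scales": [
            {"radius": 0.20, "n_samples": 8, "mlp": [64, 64]},
            {"radius": 0.40, "n_samples": 16, "mlp": [64, 64]},
        ],
    },
]
TOY_FP_MLPS = [[64, 64], [64, 64]]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters (see module docstring)."""

    n_points: int = 10000
    sa_config: list = field(default_factory=lambda: copy.deepcopy(DEFAULT_SA_CONFIG))
    fp_mlps: list = field(default_factory=lambda: copy.deepcopy(DEFAULT_FP_MLPS))
    n_classes: int = 3
    gamma: float = 2.0
    caa_enabled: bool = True
    vfl_enabled: bool = True
    vfl_form: str = "printed"  # or "original-vfl"
    caa_kernel: int = 11
    caa_reduction: int = 4
    use_rgb: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.n_classes < 2:
            raise ValueError("gamma must be >= 0 and n_classes >= 2")
        for level in self.sa_config:
            radii = [s["radius"] for s in level["scales"]]
            if radii != sorted(radii):
                raise ValueError("scale radii must increase within an SA level")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters; defaults follow the training protocol
    of the reference experiments (Adam, lr 1e-3, decay 1e-4, batch 4)."""

    batch_size: int = 4
    epochs: int = 200
    lr: float = 0.001
    weight_decay: float = 0.0001
    optimizer: str = "adam"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.batch_size, self.epochs) < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# geometric primitives


def farthest_point_sampling(
    coords: np.ndarray,
    m: int,
    seed: int | None = None,
    start_index: int | None = None,
) -> np.ndarray:
    """Greedy farthest point sampling.

    The first index is drawn from ``seed`` (or given explicitly); every
    subsequent pick maximises the minimum distance to the points already
    chosen. Ties break to the lowest index via argmax.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= N, got m={m}, N={n}")
    if start_index is None:
        start_index = int(np.random.default_rng(seed).integers(n))
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = start_index
    min_dist = np.linalg.norm(coords - coords[start_index], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(min_dist))
        chosen[i] = nxt
        min_dist = np.minimum(min_dist, np.linalg.norm(coords - coords[nxt], axis=1))
    return chosen


def ball_query(
    coords: np.ndarray, centers: np.ndarray, radius: float, s: int
) -> np.ndarray:
    """(M, s) neighbor indices within ``radius`` of each center.

    Qualifying indices are taken in ascending point-index order; when fewer
    than ``s`` qualify the first qualifying index is repeated to fill. A
    center with no neighbor in range falls back to its single nearest point.
    """
    if radius <= 0 or s < 1:
        raise ValueError("radius must be > 0 and s >= 1")
    coords = np.asarray(coords, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(centers, radius)
    out = np.empty((centers.shape[0], s), dtype=np.int64)
    empty = [i for i, nbrs in enumerate(neighborhoods) if not nbrs]
    if empty:
        _, nearest = tree.query(centers[empty])
        nearest = np.atleast_1d(nearest)
    for i, nbrs in enumerate(neighborhoods):
        if not nbrs:
            out[i] = nearest[empty.index(i)]
            continue
        nbrs = sorted(nbrs)[:s]
        out[i, : len(nbrs)] = nbrs
        out[i, len(nbrs):] = nbrs[0]
    return out


def interpolate_features(
    src_coords: np.ndarray, dst_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-square-distance weights over the 3 nearest sources.

    Returns ``(indices (N, k), weights (N, k))`` with weights summing to 1
    per destination; an exact coordinate hit receives (numerically) all of
    the weight.
    """
    src = np.asarray(src_coords, dtype=np.float64)
    dst = np.asarray(dst_coords, dtype=np.float64)
    if src.shape[0] == 0:
        raise ValueError("cannot interpolate from an empty source set")
    k = min(3, src.shape[0])
    tree = cKDTree(src)
    dist, idx = tree.query(dst, k=k)
    dist = np.atleast_2d(dist.reshape(dst.shape[0], k))
    idx = np.atleast_2d(idx.reshape(dst.shape[0], k))
    w = 1.0 / (dist**2 + 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


# ---------------------------------------------------------------------------
# losses


def varifocal_loss(p, q, gamma: float = 2.0, form: str = "printed"):
    """Varifocal loss on plain numbers/arrays (reference form, no autodiff).

    printed form: ``-q log p - (1 - q)^gamma log(1 - p)``.
    original-vfl: ``-q (q log p + (1 - q) log(1 - p))`` for q > 0 and
    ``-p^gamma log(1 - p)`` for q = 0 (the asymmetric variant in which
    gamma stays active for hard labels).
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted confidence p must lie strictly in (0, 1)")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("target confidence q must lie in [0, 1]")
    if form == "printed":
        return -q * np.log(p) - (1 - q) ** gamma * np.log(1 - p)
    if form == "original-vfl":
        pos = -q * (q * np.log(p) + (1 - q) * np.log(1 - p))
        neg = -(p**gamma) * np.log(1 - p)
        return np.where(q > 0, pos, neg)
    raise ValueError(f"unknown VFL form {form!r}")


def _vfl_loss_tensor(
    logits: Tensor, labels: np.ndarray, n_classes: int, gamma: float, form: str
) -> Tensor:
    """Mean per-class VFL with sigmoid confidences and one-hot targets."""
    p = logits.sigmoid().clip(1e-7, 1.0 - 1e-7)
    q = np.eye(n_classes)[labels]
    if form == "printed":
        loss = -(q * p.log()) - ((1 - q) ** gamma) * (1 - p).log()
    elif form == "original-vfl":
        pos = -(q * q * p.log()) - (q * (1 - q)) * (1 - p).log()
        # q = 0 entries: -p^gamma log(1-p); p^gamma = exp(gamma log p)
        neg = -((p.log() * gamma).exp() * (1 - p).log()) * (q == 0)
        loss = pos + neg
    else:
        raise ValueError(f"unknown VFL form {form!r}")
    return loss.mean()


def _ce_loss_tensor(logits: Tensor, labels: np.ndarray) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    log_probs = shifted - shifted.exp().sum(axis=-1, keepdims=True).log()
    return -log_probs.gather_rows(labels).mean()


# ---------------------------------------------------------------------------
# layers


class _SharedMLP:
    """Per-point MLP (1x1 convolutions) applied to the channel axis."""

    def __init__(self, widths: list[int], c_in: int, rng: np.random.Generator):
        self.layers: list[tuple[Tensor, Tensor]] = []
        for w in widths:
            weight = Tensor(
                rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, w)), requires_grad=True
            )
            bias = Tensor(np.zeros(w), requires_grad=True)
            self.layers.append((weight, bias))
            c_in = w
        self.c_out = c_in

    def params(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]

    def __call__(self, x: Tensor, final_relu: bool = True) -> Tensor:
        for i, (weight, bias) in enumerate(self.layers):
            x = x @ weight + bias
            if final_relu or i < len(self.layers) - 1:
                x = x.relu()
        return x


class CAABlock:
    """Context-anchor attention over an (H, W, C) feature map.

    Pipeline: global average pool -> 1x1 conv (channel reduction) ->
    horizontal depthwise conv -> vertical depthwise conv -> 1x1 conv
    (fusion back to C channels) -> sigmoid. The attention is broadcast to
    the input's spatial shape, so every output value lies strictly in
    (0, 1) and the spatial dimensions match the input.
    """

    def __init__(self, c: int, reduction: int, kernel: int, rng: np.random.Generator):
        c_mid = max(c // reduction, 4)
        self.w1 = Tensor(rng.normal(0, np.sqrt(2.0 / c), (c, c_mid)), requires_grad=True)
        self.b1 = Tensor(np.zeros(c_mid), requires_grad=True)
        self.kh = Tensor(rng.normal(0, 1.0 / kernel, (kernel, c_mid)), requires_grad=True)
        self.kv = Tensor(rng.normal(0, 1.0 / kernel, (kernel, c_mid)), requires_grad=True)
        self.w2 = Tensor(rng.normal(0, np.sqrt(2.0 / c_mid), (c_mid, c)), requires_grad=True)
        self.b2 = Tensor(np.zeros(c), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.kh, self.kv, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(0, 1), keepdims=True)      # (1, 1, C)
        a = pooled @ self.w1 + self.b1                   # channel reduction
        a = a.dwconv(self.kh, axis=1)                    # horizontal
        a = a.dwconv(self.kv, axis=0)                    # vertical
        a = a @ self.w2 + self.b2                        # fusion
        att = a.sigmoid()
        h, w = x.shape[0], x.shape[1]
        return att * Tensor(np.ones((h, w, 1)))          # broadcast to (H, W, C)


class _SALevel:
    """One set-abstraction level with multi-scale grouping and CAApoint."""

    def __init__(self, level_cfg: dict, c_in: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        self.n_centers = level_cfg["n_centers"]
        self.scales = []
        self.c_out = 0
        for scale in level_cfg["scales"]:
            mlp = _SharedMLP(scale["mlp"], c_in + 3, rng)
            caa = (
                CAABlock(mlp.c_out, cfg.caa_reduction, cfg.caa_kernel, rng)
                if cfg.caa_enabled
                else None
            )
            self.scales.append((scale["radius"], scale["n_samples"], mlp, caa))
            self.c_out += mlp.c_out

    def params(self) -> list[Tensor]:
        out = []
        for _, _, mlp, caa in self.scales:
            out += mlp.params()
            if caa is not None:
                out += caa.params()
        return out

    def __call__(self, coords: np.ndarray, feats: Tensor, rng: np.random.Generator):
        m = min(self.n_centers, coords.shape[0])
        centers_idx = farthest_point_sampling(
            coords, m, start_index=int(rng.integers(coords.shape[0]))
        )
        centers = coords[centers_idx]
        outputs = []
        for radius, s, mlp, caa in self.scales:
            idx = ball_query(coords, centers, radius, s)
            rel = coords[idx] - centers[:, None, :]          # (M, S, 3)
            grouped = concat([Tensor(rel), feats.gather(idx)], axis=-1)
            encoded = mlp(grouped)                           # (M, S, C')
            if caa is not None:
                encoded = encoded * caa(encoded)
            outputs.append(encoded.max(axis=1))              # pool over samples
        return centers, concat(outputs, axis=-1)


class _FPLevel:
    """Feature propagation: 3-NN inverse-distance interpolation + unit MLP."""

    def __init__(self, widths: list[int], c_in: int, rng: np.random.Generator):
        self.mlp = _SharedMLP(widths, c_in, rng)
        self.c_out = self.mlp.c_out

    def params(self) -> list[Tensor]:
        return self.mlp.params()

    def __call__(self, src_coords, src_feats: Tensor, dst_coords,
                 skip_feats: Tensor | None) -> Tensor:
        idx, w = interpolate_features(src_coords, dst_coords)
        gathered = src_feats.gather(idx)                     # (N, k, C)
        interp = (gathered * Tensor(w[:, :, None])).sum(axis=1)
        if skip_feats is not None:
            interp = concat([interp, skip_feats], axis=-1)
        return self.mlp(interp)


# ---------------------------------------------------------------------------
# the estimator


class CAVFPointNetSegmenter(ClassifierMixin, BaseEstimator):
    """Semantic organ segmentation of plant point clouds.

    sklearn-style estimator: ``fit(X, y)`` takes a list of per-cloud
    feature arrays (``(N_i, 3)`` xyz or ``(N_i, 6)`` xyz+rgb, rgb in
    [0, 255]) and a list of per-point integer labels; ``predict(X)``
    returns a list of label arrays. Fitted state lives in ``params_``
    (weights), ``history_`` (per-epoch losses/accuracies) and
    ``classes_``.
    """

    def __init__(
        self,
        n_points: int = 10000,
        sa_config: list | None = None,
        fp_mlps: list | None = None,
        n_classes: int = 3,
        gamma: float = 2.0,
        caa_enabled: bool = True,
        vfl_enabled: bool = True,
        vfl_form: str = "printed",
        caa_kernel: int = 11,
        caa_reduction: int = 4,
        use_rgb: bool = True,
        batch_size: int = 4,
        epochs: int = 200,
        lr: float = 0.001,
        lr_warmup: int = 0,
        weight_decay: float = 0.0001,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_points = n_points
        self.sa_config = sa_config
        self.fp_mlps = fp_mlps
        self.n_classes = n_classes
        self.gamma = gamma
        self.caa_enabled = caa_enabled
        self.vfl_enabled = vfl_enabled
        self.vfl_form = vfl_form
        self.caa_kernel = caa_kernel
        self.caa_reduction = caa_reduction
        self.use_rgb = use_rgb
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr = lr
        self.lr_warmup = lr_warmup
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    @classmethod
    def from_configs(
        cls, cfg: NetworkConfig, tcfg: TrainConfig
    ) -> "CAVFPointNetSegmenter":
        return cls(
            n_points=cfg.n_points,
            sa_config=cfg.sa_config,
            fp_mlps=cfg.fp_mlps,
            n_classes=cfg.n_classes,
            gamma=cfg.gamma,
            caa_enabled=cfg.caa_enabled,
            vfl_enabled=cfg.vfl_enabled,
            vfl_form=cfg.vfl_form,
            caa_kernel=cfg.caa_kernel,
            caa_reduction=cfg.caa_reduction,
            use_rgb=cfg.use_rgb,
            batch_size=tcfg.batch_size,
            epochs=tcfg.epochs,
            lr=tcfg.lr,
            weight_decay=tcfg.weight_decay,
            validation_fraction=tcfg.split[1],
            random_state=tcfg.seed,
        )

    def _build(self, rng: np.random.Generator) -> None:
        sa_config = self.sa_config if self.sa_config is not None else DEFAULT_SA_CONFIG
        fp_mlps = self.fp_mlps if self.fp_mlps is not None else DEFAULT_FP_MLPS
        cfg = NetworkConfig(
            n_points=self.n_points,
            sa_config=copy.deepcopy(sa_config),
            fp_mlps=copy.deepcopy(fp_mlps),
            n_classes=self.n_classes,
            gamma=self.gamma,
            caa_enabled=self.caa_enabled,
            vfl_enabled=self.vfl_enabled,
            vfl_form=self.vfl_form,
            caa_kernel=self.caa_kernel,
            caa_reduction=self.caa_reduction,
            use_rgb=self.use_rgb,
        )
        c_in = 6 if self.use_rgb else 3
        self._sa_levels: list[_SALevel] = []
        channels = [c_in]
        for level_cfg in cfg.sa_config:
            level = _SALevel(level_cfg, channels[-1], cfg, rng)
            self._sa_levels.append(level)
            channels.append(level.c_out)
        if len(cfg.fp_mlps) != len(self._sa_levels):
            raise ValueError("need one FP width list per SA level")
        self._fp_levels: list[_FPLevel] = []
        c_src = channels[-1]
        for li in reversed(range(len(self._sa_levels))):
            fp = _FPLevel(cfg.fp_mlps[li], c_src + channels[li], rng)
            self._fp_levels.append(fp)
            c_src = fp.c_out
        head_rng = rng
        self._head = _SharedMLP([max(c_src // 2, self.n_classes), self.n_classes],
                                c_src, head_rng)
        self.params_ = []
        for level in self._sa_levels:
            self.params_ += level.params()
        for fp in self._fp_levels:
            self.params_ += fp.params()
        self.params_ += self._head.params()

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _normalize(coords: np.ndarray) -> np.ndarray:
        centered = coords - coords.mean(axis=0)
        scale = np.linalg.norm(centered, axis=1).max()
        return centered / (scale if scale > 0 else 1.0)

    def _features(self, cloud: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cloud = np.asarray(cloud, dtype=np.float64)
        coords = self._normalize(cloud[:, :3])
        if self.use_rgb:
            if cloud.shape[1] >= 6:
                rgb = cloud[:, 3:6] / 255.0
            else:
                rgb = np.zeros_like(coords)
            feats = np.concatenate([coords, rgb], axis=1)
        else:
            feats = coords
        return coords, feats

    def forward_logits(self, cloud: np.ndarray, rng: np.random.Generator) -> Tensor:
        """Per-point class logits for one cloud (already <= n_points)."""
        coords, feats = self._features(cloud)
        xyz = [coords]
        features = [Tensor(feats)]
        for level in self._sa_levels:
            centers, encoded = level(xyz[-1], features[-1], rng)
            xyz.append(centers)
            features.append(encoded)
        current = features[-1]
        for i, fp in enumerate(self._fp_levels):
            li = len(self._sa_levels) - 1 - i
            current = fp(xyz[li + 1], current, xyz[li], features[li])
        return self._head(current, final_relu=False)

    def _loss(self, logits: Tensor, labels: np.ndarray) -> Tensor:
        if self.vfl_enabled:
            return _vfl_loss_tensor(
                logits, labels, self.n_classes, self.gamma, self.vfl_form
            )
        return _ce_loss_tensor(logits, labels)

    # -- training ----------------------------------------------------------

    def fit(self, X: list[np.ndarray], y: list[np.ndarray]):
        """Train on a list of clouds; records per-epoch history.

        Each cloud is randomly subsampled once (seeded) to ``n_points``.
        When ``validation_fraction`` > 0 and there are enough clouds, a
        validation subset is held out and the weights with the best
        validation loss are restored at the end.
        """
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of clouds")
        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        self.classes_ = np.arange(self.n_classes)

        clouds, labels = [], []
        for cloud, lab in zip(X, y):
            cloud = np.asarray(cloud, dtype=np.float64)
            lab = np.asarray(lab, dtype=np.int64)
            if cloud.shape[0] > self.n_points:
                pick = rng.choice(cloud.shape[0], self.n_points, replace=False)
                cloud, lab = cloud[pick], lab[pick]
            clouds.append(cloud)
            labels.append(lab)

        n_val = int(round(self.validation_fraction * len(clouds)))
        order = rng.permutation(len(clouds))
        val_ids = order[:n_val]
        train_ids = order[n_val:]
        if train_ids.size == 0:
            train_ids, val_ids = order, np.empty(0, dtype=np.int64)

        opt = Adam(self.params_, lr=self.lr, weight_decay=self.weight_decay)
        self.history_ = []
        best_val, best_weights = np.inf, None
        for epoch in range(self.epochs):
            if self.lr_warmup > 0:
                # linear learning-rate warmup stabilises the first epochs
                opt.lr = self.lr * min(1.0, (epoch + 1) / self.lr_warmup)
            perm = rng.permutation(train_ids)
            losses, correct, total = [], 0, 0
            for start in range(0, perm.size, self.batch_size):
                batch = perm[start : start + self.batch_size]
                opt.zero_grad()
                batch_losses = []
                for ci in batch:
                    logits = self.forward_logits(clouds[ci], rng)
                    loss = self._loss(logits, labels[ci])
                    batch_losses.append(loss)
                    pred = logits.data.argmax(axis=1)
                    correct += int((pred == labels[ci]).sum())
                    total += labels[ci].size
                batch_loss = batch_losses[0]
                for extra in batch_losses[1:]:
                    batch_loss = batch_loss + extra
                batch_loss = batch_loss * (1.0 / len(batch_losses))
                batch_loss.backward()
                opt.step()
                losses.append(float(batch_loss.data))
            # history records an end-of-epoch evaluation pass over the
            # training clouds (the running within-epoch mean is also kept)
            train_loss, train_oa = self._evaluate(
                [clouds[i] for i in train_ids], [labels[i] for i in train_ids]
            )
            record = {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_oa": train_oa,
                "running_loss": float(np.mean(losses)),
                "running_oa": correct / max(total, 1),
            }
            if val_ids.size:
                val_loss, val_oa = self._evaluate(
                    [clouds[i] for i in val_ids], [labels[i] for i in val_ids]
                )
                record["val_loss"], record["val_oa"] = val_loss, val_oa
                if val_loss < best_val:
                    best_val = val_loss
                    best_weights = [p.data.copy() for p in self.params_]
            self.history_.append(record)
        if best_weights is not None:
            for p, w in zip(self.params_, best_weights):
                p.data = w
        return self

    def _evaluate(self, clouds, labels) -> tuple[float, float]:
        rng = np.random.default_rng(self.random_state + 1)
        losses, correct, total = [], 0, 0
        for cloud, lab in zip(clouds, labels):
            logits = self.forward_logits(cloud, rng)
            losses.append(float(self._loss(logits, lab).data))
            correct += int((logits.data.argmax(axis=1) == lab).sum())
            total += lab.size
        return float(np.mean(losses)), correct / max(total, 1)

    # -- inference ---------------------------------------------------------

    def predict(self, X: list[np.ndarray]) -> list[np.ndarray]:
        return [self.predict_one(cloud) for cloud in X]

    def predict_one(self, cloud: np.ndarray) -> np.ndarray:
        """Labels for one cloud of any size.

        Clouds larger than ``n_points`` are processed on a seeded random
        subsample and the remaining points take the label of their nearest
        sampled neighbor. Deterministic for fixed weights and seed.
        """
        cloud = np.asarray(cloud, dtype=np.float64)
        if cloud.shape[0] == 0:
            raise ValueError("cannot predict on an empty cloud")
        rng = np.random.default_rng(self.random_state + 2)
        if cloud.shape[0] > self.n_points:
            pick = rng.choice(cloud.shape[0], self.n_points, replace=False)
        else:
            pick = np.arange(cloud.shape[0])
        logits = self.forward_logits(cloud[pick], rng)
        sub_labels = logits.data.argmax(axis=1)
        if pick.size == cloud.shape[0]:
            return sub_labels
        tree = cKDTree(cloud[pick, :3])
        _, nearest = tree.query(cloud[:, :3])
        return sub_labels[nearest]


# ---------------------------------------------------------------------------
# functional wrappers


def train_model(
    dataset: list[LabeledCloud],
    cfg: NetworkConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[CAVFPointNetSegmenter, list[dict]]:
    """Train on labelled clouds with an 8:1:1-style split.

    With at least 3 clouds the configured split fractions are applied
    (counts rounded, at least one training cloud); smaller datasets train
    on everything.
    """
    if not dataset:
        raise ValueError("empty dataset")
    cfg = cfg or NetworkConfig()
    tcfg = tcfg or TrainConfig()
    model = CAVFPointNetSegmenter.from_configs(cfg, tcfg)
    X = [
        np.concatenate(
            [lc.cloud.coords,
             (lc.cloud.colors if lc.cloud.has_colors
              else np.zeros((len(lc), 3)))],
            axis=1,
        )
        for lc in dataset
    ]
    y = [lc.semantic for lc in dataset]
    model.fit(X, y)
    return model, model.history_


def split_dataset(
    n: int, split: tuple[float, float, float], seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/val/test index split with rounded fractions."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]


def predict_semantics(
    cloud: PointCloud, model: CAVFPointNetSegmenter
) -> LabeledCloud:
    """Semantic labels for every point of a cloud."""
    feats = cloud.coords
    if cloud.has_colors:
        feats = np.concatenate([cloud.coords, cloud.colors], axis=1)
    labels = model.predict_one(feats)
    return LabeledCloud(cloud, labels)
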