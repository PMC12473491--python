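"""Filtering cascade and scale calibration for raw plant reconstructions.

A dense multi-view reconstruction of a potted plant carries sparse
reconstruction flotsam, soil/background points and far too many vertices.
The cleaning cascade runs, in order:

1. local-density filtering (drop the sparsest points),
2. excess-green color filtering (keep ExG > threshold, the vegetation),
3. statistical outlier removal (drop points whose mean neighbor distance
   is anomalous),
4. voxel-grid downsampling (one centroid per occupied voxel).

Scale calibration converts reconstruction units to centimetres using a
cube of known physical edge length scanned with the plant:
``r = h_real / h_reconstructed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .containers import PointCloud


def _knn_mean_distance(coords: np.ndarray, k: int) -> np.ndarray:
    """Mean distance of every point to its k nearest neighbors (self excluded)."""
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return dist[:, 1:].mean(axis=1)


def local_density(cloud: PointCloud, k: int) -> np.ndarray:
    """Per-point density = reciprocal of the mean k-NN distance.

    Duplicated points (zero mean neighbor distance) would be infinitely
    dense; they are assigned the maximum finite density of the cloud so
    they always survive density filtering without propagating infinities.
    """
    mean_dist = _knn_mean_distance(cloud.coords, k)
    with np.errstate(divide="ignore"):
        density = 1.0 / mean_dist
    finite = np.isfinite(density)
    if not finite.all():
        if not finite.any():
            raise ValueError("all points are duplicates; density undefined")
        density[~finite] = density[finite].max()
    return density


def density_filter(
    cloud: PointCloud, k: int = 20, keep_percentile: float = 0.95
) -> PointCloud:
    """Keep the densest ``keep_percentile`` fraction of points.

    Points whose density equals the threshold are kept (ties survive), so
    ``keep_percentile=1`` is the identity. Order is preserved.
    """
    if not 0 < keep_percentile <= 1:
        raise ValueError("keep_percentile must lie in (0, 1]")
    density = local_density(cloud, k)
    threshold = np.quantile(density, 1.0 - keep_percentile)
    return cloud.select(density >= threshold)


def exg(colors: np.ndarray) -> np.ndarray:
    """Excess-green index ExG = 2G - R - B, in [-510, 510]."""
    c = np.asarray(colors, dtype=np.float64)
    return 2.0 * c[:, 1] - c[:, 0] - c[:, 2]


def nexg(colors: np.ndarray) -> np.ndarray:
    """Normalised excess green (2G - R - B) / (R + G + B); 0 for black."""
    c = np.asarray(colors, dtype=np.float64)
    total = c.sum(axis=1)
    out = np.zeros(c.shape[0])
    nz = total > 0
    out[nz] = (2.0 * c[nz, 1] - c[nz, 0] - c[nz, 2]) / total[nz]
    return out


def color_filter(
    cloud: PointCloud, threshold: float = 30.0, use_nexg: bool = False
) -> PointCloud:
    """Keep points whose green index is *strictly* greater than threshold.

    The default index is ExG with the vegetation threshold 30; NExG (with a
    correspondingly rescaled threshold) is available for robustness checks.
    """
    if not cloud.has_colors:
        raise ValueError("color_filter requires a cloud with colors")
    index = nexg(cloud.colors) if use_nexg else exg(cloud.colors)
    return cloud.select(index > threshold)


def statistical_outlier_removal(
    cloud: PointCloud, n_neighbors: int = 5, std_coeff: float = 0.8
) -> PointCloud:
    """Classic statistical outlier removal.

    A point is removed iff its mean distance to its ``n_neighbors`` nearest
    neighbors exceeds ``mu + std_coeff * sigma`` where mu/sigma are the
    global mean and standard deviation of those per-point mean distances.
    """
    mean_dist = _knn_mean_distance(cloud.coords, n_neighbors)
    mu, sigma = mean_dist.mean(), mean_dist.std()
    return cloud.select(mean_dist <= mu + std_coeff * sigma)


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """One output point per occupied voxel: the centroid of its members.

    Voxel indices are ``floor((coord - min_corner) / voxel)`` (half-open
    cells); output order follows first occurrence, so a cloud whose point
    spacing already exceeds the voxel size passes through unchanged.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if len(cloud) == 0:
        return cloud.copy()
    idx = np.floor((cloud.coords - cloud.coords.min(axis=0)) / voxel).astype(np.int64)
    _, first, inverse = np.unique(
        idx, axis=0, return_index=True, return_inverse=True
    )
    # renumber voxels by first occurrence so output order is deterministic
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    groups = rank[inverse]
    counts = np.bincount(groups).astype(np.float64)
    coords = np.zeros((order.size, 3))
    for j in range(3):
        coords[:, j] = np.bincount(groups, weights=cloud.coords[:, j]) / counts
    colors = None
    if cloud.has_colors:
        colors = np.zeros((order.size, 3))
        for j in range(3):
            colors[:, j] = np.bincount(groups, weights=cloud.colors[:, j]) / counts
        colors = np.clip(np.rint(colors), 0, 255).astype(np.uint8)
    return PointCloud(coords, colors)


def scale_factor(h_real: float, h_reconstructed: float) -> float:
    """Scale factor r = real edge length / reconstructed edge length (cm/unit)."""
    if h_real <= 0 or h_reconstructed <= 0:
        raise ValueError("edge lengths must be positive")
    return h_real / h_reconstructed


def cube_edge_length(cube_cloud: PointCloud) -> float:
    """Edge length of the calibration cube in reconstruction units.

    The mean of the three axis-aligned bounding-box extents; robust to the
    cube being incompletely sampled on one face.
    """
    if len(cube_cloud) == 0:
        raise ValueError("empty cube cloud")
    extents = cube_cloud.coords.max(axis=0) - cube_cloud.coords.min(axis=0)
    return float(extents.mean())


@dataclass
class PreprocessParams:
    """Tunables of the cleaning cascade (see module docstring for stages)."""

    k_density: int = 20
    density_keep_percentile: float = 0.95
    exg_threshold: float = 30.0
    use_nexg: bool = False
    sor_neighbors: int = 5
    sor_std_coeff: float = 0.8
    voxel_size: float = 0.04

    def __post_init__(self) -> None:
        if self.k_density < 1:
            raise ValueError("k_density must be >= 1")
        if not 0 < self.density_keep_percentile <= 1:
            raise ValueError("density_keep_percentile must lie in (0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


class PointCloudPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer running the full cleaning cascade.

    ``transform`` maps a :class:`PointCloud` to its cleaned version and
    records per-stage point counts in ``stage_counts_``. Stages can be
    switched off individually (``voxel_size=None`` skips downsampling,
    ``exg_threshold=None`` skips color filtering, and so on).
    """

    def __init__(
        self,
        k_density: int | None = 20,
        density_keep_percentile: float = 0.95,
        exg_threshold: float | None = 30.0,
        use_nexg: bool = False,
        sor_neighbors: int | None = 5,
        sor_std_coeff: float = 0.8,
        voxel_size: float | None = 0.04,
    ):
        self.k_density = k_density
        self.density_keep_percentile = density_keep_percentile
        self.exg_threshold = exg_threshold
        self.use_nexg = use_nexg
        self.sor_neighbors = sor_neighbors
        self.sor_std_coeff = sor_std_coeff
        self.voxel_size = voxel_size

    def fit(self, X: PointCloud, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X: PointCloud) -> PointCloud:
        counts = [("input", len(X))]
        cloud = X
        if self.k_density is not None:
            cloud = density_filter(cloud, self.k_density, self.density_keep_percentile)
            counts.append(("density", len(cloud)))
        if self.exg_threshold is not None and cloud.has_colors:
            cloud = color_filter(cloud, self.exg_threshold, self.use_nexg)
            counts.append(("color", len(cloud)))
        if self.sor_neighbors is not None:
            cloud = statistical_outlier_removal(
                cloud, self.sor_neighbors, self.sor_std_coeff
            )
            counts.append(("statistical", len(cloud)))
        if self.voxel_size is not None:
            cloud = voxel_downsample(cloud, self.voxel_size)
            counts.append(("voxel", len(cloud)))
        self.stage_counts_ = counts
        return cloud

    @classmethod
    def from_params(cls, params: PreprocessParams) -> "PointCloudPreprocessor":
        return cls(
            k_density=params.k_density,
            density_keep_percentile=params.density_keep_percentile,
            exg_threshold=params.exg_threshold,
            use_nexg=params.use_nexg,
            sor_neighbors=params.sor_neighbors,
            sor_std_coeff=params.sor_std_coeff,
            voxel_size=params.voxel_size,
        )


def preprocess(cloud: PointCloud, params: PreprocessParams | None = None) -> PointCloud:
    """Run the full cascade with :class:`PreprocessParams` defaults."""
    params = params or PreprocessParams()
    return PointCloudPreprocessor.from_params(params).transform(cloud)
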