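"""Leaf instance segmentation by curvature gating plus density clustering.

Where two leaves touch, the surface folds: the local normal direction
changes abruptly, so a curvature statistic built from normal-vector
variation spikes along the contact region. The pipeline is

1. estimate oriented unit normals from local PCA,
2. per-point curvature = mean norm of the difference between the point's
   normal and its k neighbors' normals,
3. remove points whose curvature exceeds a threshold (the contact areas),
4. DBSCAN on the remaining points: each spatially connected dense blob is
   one leaf; sparse leftovers become noise (-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components, minimum_spanning_tree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .containers import LEAF, NOISE_INSTANCE, LabeledCloud, PointCloud


@dataclass
class ClusterParams:
    """Tunables of the leaf instance stage.

    ``threshold`` is in curvature units (the normal-difference statistic is
    dimensionless, bounded by 2); ``eps`` is in reconstruction units.
    Defaults are the balanced operating point of the parameter study:
    threshold 0.2, eps 0.006, min_pts 10.
    """

    curvature_k: int = 30
    threshold: float = 0.2
    eps: float = 0.006
    min_pts: int = 10
    reassign_contacts: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.eps <= 0 or self.min_pts < 1:
            raise ValueError("invalid clustering parameters")


def knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """(N, k) indices of each point's k nearest neighbors, self excluded."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    return idx[:, 1:]


def estimate_normals(cloud: PointCloud, k: int = 30) -> np.ndarray:
    """Unit normals from the smallest eigenvector of the local k-NN covariance.

    PCA normals carry an arbitrary sign, which would corrupt any statistic
    built from normal *differences*. Signs are made consistent by
    propagating orientation along a minimum spanning tree of the k-NN graph
    (edge cost 1 - |n_i . n_j|), then each connected component is flipped,
    if needed, so normals point outward (non-negative mean dot product with
    the centroid-to-point direction).
    """
    coords = cloud.coords
    n = coords.shape[0]
    if k < 3 or n <= k:
        raise ValueError(f"need N > k >= 3, got N={n}, k={k}")
    idx = knn_indices(coords, k)
    neighborhoods = coords[idx]  # (N, k, 3)
    centered = neighborhoods - neighborhoods.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    # orientation consistency: MST propagation over the k-NN graph
    rows = np.repeat(np.arange(n), idx.shape[1])
    cols = idx.reshape(-1)
    cost = 1.0 - np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    graph = coo_matrix((cost + 1e-12, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    sym = mst + mst.T
    n_comp, comp = connected_components(sym, directed=False)
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        root = members[0]
        order, pred = breadth_first_order(sym, root, directed=False)
        for node in order[1:]:
            if np.dot(normals[node], normals[pred[node]]) < 0:
                normals[node] = -normals[node]
        outward = coords[members] - coords.mean(axis=0)
        if np.einsum("ij,ij->", normals[members], outward) < 0:
            normals[members] = -normals[members]
    return normals


def curvature(normals: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Curvature_i = (1/k) sum_j || n_j - n_i || over the k neighborhood normals."""
    normals = np.asarray(normals, dtype=np.float64)
    neighbors = np.asarray(neighbors, dtype=np.int64)
    if neighbors.ndim != 2 or neighbors.shape[1] < 1:
        raise ValueError("each point needs a non-empty neighborhood")
    diffs = normals[neighbors] - normals[:, None, :]
    return np.linalg.norm(diffs, axis=2).mean(axis=1)


def remove_contact_points(
    cloud: PointCloud, curv: np.ndarray, threshold: float
) -> tuple[PointCloud, np.ndarray]:
    """Split into (kept cloud with curvature <= threshold, removed indices)."""
    curv = np.asarray(curv, dtype=np.float64).reshape(-1)
    if curv.shape[0] != len(cloud):
        raise ValueError("curvature length does not match cloud")
    removed = np.flatnonzero(curv > threshold)
    kept = cloud.select(curv <= threshold)
    return kept, removed


def dbscan_cluster(coords: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Standard DBSCAN instance labels; noise = -1.

    Core points have >= min_pts points (self included) within eps; clusters
    are connected components of core points plus reachable border points.
    Cluster ids are renumbered 0..C-1 by their first member's index so the
    labelling is independent of internal processing order.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    if coords.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    labels = np.full(raw.shape[0], NOISE_INSTANCE, dtype=np.int64)
    next_id = 0
    remap: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab < 0:
            continue
        if lab not in remap:
            remap[lab] = next_id
            next_id += 1
        labels[i] = remap[lab]
    return labels


class LeafInstanceSegmenter(ClusterMixin, BaseEstimator):
    """sklearn-style clusterer: leaf coords in, instance labels out.

    ``fit`` runs normals -> curvature -> contact removal -> DBSCAN and
    stores ``labels_`` (instance id per input point, -1 for contact points
    and DBSCAN noise), ``curvature_`` and ``contact_indices_``. With
    ``reassign_contacts=True`` removed contact points are given the
    majority instance among their nearest retained neighbors afterwards.
    """

    def __init__(
        self,
        curvature_k: int = 30,
        threshold: float = 0.2,
        eps: float = 0.006,
        min_pts: int = 10,
        reassign_contacts: bool = False,
    ):
        self.curvature_k = curvature_k
        self.threshold = threshold
        self.eps = eps
        self.min_pts = min_pts
        self.reassign_contacts = reassign_contacts

    def fit(self, X, y=None):
        coords = X.coords if isinstance(X, PointCloud) else np.asarray(X, dtype=np.float64)
        if coords.shape[0] == 0:
            raise ValueError("cannot segment an empty leaf cloud")
        cloud = PointCloud(coords)
        normals = estimate_normals(cloud, self.curvature_k)
        neigh = knn_indices(coords, self.curvature_k)
        curv = curvature(normals, neigh)
        kept_mask = curv <= self.threshold
        labels = np.full(coords.shape[0], NOISE_INSTANCE, dtype=np.int64)
        kept_idx = np.flatnonzero(kept_mask)
        if kept_idx.size:
            labels[kept_idx] = dbscan_cluster(
                coords[kept_idx], self.eps, self.min_pts
            )
        contact_idx = np.flatnonzero(~kept_mask)
        if self.reassign_contacts and contact_idx.size and kept_idx.size:
            assigned = kept_idx[labels[kept_idx] >= 0]
            if assigned.size:
                k = min(self.min_pts, assigned.size)
                nn = NearestNeighbors(n_neighbors=k).fit(coords[assigned])
                _, near = nn.kneighbors(coords[contact_idx])
                votes = labels[assigned][near]
                for row, i in enumerate(contact_idx):
                    vals, counts = np.unique(votes[row], return_counts=True)
                    labels[i] = vals[np.argmax(counts)]
        self.labels_ = labels
        self.curvature_ = curv
        self.normals_ = normals
        self.contact_indices_ = contact_idx
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def segment_leaves(
    leaf_cloud: PointCloud, params: ClusterParams | None = None
) -> LabeledCloud:
    """Run the full instance pipeline on a leaf-only cloud.

    Returns a :class:`LabeledCloud` whose semantic labels are all ``leaf``
    and whose instance column carries the cluster ids (-1 = contact/noise).
    """
    params = params or ClusterParams()
    seg = LeafInstanceSegmenter(
        curvature_k=params.curvature_k,
        threshold=params.threshold,
        eps=params.eps,
        min_pts=params.min_pts,
        reassign_contacts=params.reassign_contacts,
    )
    labels = seg.fit_predict(leaf_cloud)
    semantic = np.full(len(leaf_cloud), LEAF, dtype=np.int64)
    return LabeledCloud(leaf_cloud, semantic, labels)
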