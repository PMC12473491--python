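"""Plant coordinate calibration and organ-level trait extraction.

The stem's principal direction defines the plant Z-axis; all traits are
then simple geometry in that frame, converted to real units by the
calibration scale factor ``r`` (cm per reconstruction unit):

- plant height: Z extent of the axis-aligned bounding box (cm),
- stem diameter: least-squares circle fit to the XY projection of a thin
  slice 2 cm above the ground (mm),
- leaf length: accumulated length of a greedy midrib walk between the two
  mutually farthest leaf points (cm),
- leaf width: extent across the leaf (cm),
- leaf angle: angle between the petiole's principal direction and the stem
  axis (degrees),
- leaf area: summed Delaunay triangle areas after projection onto the
  leaf's principal plane (cm^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .containers import (
    LEAF,
    PETIOLE,
    STEM,
    LabeledCloud,
    LeafTraits,
    PointCloud,
    TraitReport,
)


@dataclass
class PlantFrame:
    """Rigid transform into the plant coordinate system.

    ``apply`` maps reconstruction coordinates to a frame whose +Z is the
    stem axis with the ground (stem base) at Z = 0.
    """

    rotation: np.ndarray
    translation: np.ndarray
    stem_axis: np.ndarray = field(default=None)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=np.float64) @ self.rotation.T + self.translation


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate point set: no principal direction")
    return vt[0]


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``axis`` (unit) to +Z (Rodrigues formula)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about X
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def calibrate_frame(stem_cloud: PointCloud) -> PlantFrame:
    """PCA of the stem defines the plant Z-axis.

    The axis sign is chosen so the stem end nearest the original
    minimum-height end of the cloud maps to low Z (ground at the bottom);
    the stem base point maps to the origin.
    """
    coords = stem_cloud.coords
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 stem points to calibrate a frame")
    axis = _principal_axis(coords)
    proj = coords @ axis
    # orient the axis "up": growing projection should track the original height
    if np.cov(proj, coords[:, 2])[0, 1] < 0:
        axis = -axis
    rotation = _rotation_to_z(axis)
    rotated = coords @ rotation.T
    # XY origin on the stem axis (centroid of the radially symmetric stem),
    # Z origin at the stem base so the ground sits at Z = 0
    translation = -np.array(
        [rotated[:, 0].mean(), rotated[:, 1].mean(), rotated[:, 2].min()]
    )
    return PlantFrame(rotation=rotation, translation=translation, stem_axis=axis)


def _denoise_if_thick(coords: np.ndarray, k: int = 30) -> np.ndarray:
    """Replace points by k-NN centroids when the surface is noise-thickened.

    A clean surface sample is locally planar: the smallest eigenvalue of a
    small neighborhood's covariance is negligible against the in-plane
    spread. When reconstruction noise thickens the sheet, neighborhoods
    become nearly isotropic. If the median local thickness ratio
    ``sqrt(lambda_3 / lambda_2)`` exceeds 0.4, each point is replaced by
    the centroid of its k nearest neighbors, shrinking the noise by
    ~sqrt(k) while preserving the surface. Clean clouds pass through
    untouched, so noiseless accuracy is unaffected.
    """
    n = coords.shape[0]
    if n <= k + 1:
        return coords
    tree = cKDTree(coords)
    nn_dist, _ = tree.query(coords, k=2)
    spacing = float(np.median(nn_dist[:, 1]))
    probe = coords[:: max(n // 400, 1)]
    _, idx = tree.query(probe, k=min(20, n))
    neigh = coords[idx]
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / idx.shape[1]
    eig = np.maximum(np.linalg.eigvalsh(cov), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.sqrt(eig[:, 0] / np.where(eig[:, 1] > 0, eig[:, 1], np.inf))
    isotropic = float(np.median(ratio)) > 0.4
    thick = float(np.median(np.sqrt(eig[:, 0]))) > 0.5 * spacing
    if not (isotropic and thick):
        return coords
    _, idx = tree.query(coords, k=k)
    return coords[idx].mean(axis=1)


def plant_height(cloud: PointCloud, frame: PlantFrame, r: float) -> float:
    """Bounding-box Z extent in the plant frame, in cm."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    z = frame.apply(cloud.coords)[:, 2]
    return float((z.max() - z.min()) * r)


def fit_circle(points2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares (Kasa) circle fit; exact on a true circle."""
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a circle")
    a = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(pts.shape[0])])
    b = (pts**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-10 * sv[0]:
        raise ValueError("collinear points: circle fit is degenerate")
    center = sol[:2]
    radius = float(np.sqrt(sol[2] + center @ center))
    return center, radius


def _debias_circle_radius(points2d: np.ndarray) -> float:
    """Noise-corrected circle radius.

    With isotropic 2D noise of variance ``sigma^2`` per axis, radial
    distances from the center follow a Rice distribution whose moments
    satisfy ``E[d^2] = rho^2 + 2 sigma^2`` and
    ``E[d^4] = rho^4 + 8 rho^2 sigma^2 + 8 sigma^4``. Solving the two
    moment equations yields an estimate of the true radius ``rho`` that is
    exact for noiseless data (where it reduces to the fitted radius) and
    removes the upward bias the algebraic fit suffers when the noise is
    comparable to the radius.
    """
    center, _ = fit_circle(points2d)
    d2 = ((np.asarray(points2d, dtype=np.float64) - center) ** 2).sum(axis=1)
    m2 = float(d2.mean())
    m4 = float((d2**2).mean())
    disc = max(2.0 * m2**2 - m4, 0.0)
    noise_var = max((m2 - np.sqrt(disc)) / 2.0, 0.0)
    return float(np.sqrt(max(m2 - 2.0 * noise_var, 1e-12 * m2)))


def stem_diameter(
    stem_cloud: PointCloud,
    frame: PlantFrame,
    r: float,
    slice_height: float = 2.0,
    slab: float = 0.4,
    debias: bool = True,
) -> float:
    """Diameter (mm) of the circle fitted to a slice ``slice_height`` cm
    above the ground, of thickness ``slab`` cm.

    With ``debias`` (default) the fitted radius is corrected for the
    upward bias caused by reconstruction noise via the Rician moment
    relation; the correction vanishes on clean data.
    """
    pts = frame.apply(stem_cloud.coords)
    z_cm = pts[:, 2] * r
    mask = np.abs(z_cm - slice_height) <= slab / 2
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} stem points in the slice at "
            f"{slice_height} cm; increase the slab thickness"
        )
    if debias:
        radius = _debias_circle_radius(pts[mask, :2])
    else:
        _, radius = fit_circle(pts[mask, :2])
    return float(2.0 * radius * r * 10.0)  # units -> cm -> mm


def _farthest_pair(coords: np.ndarray) -> tuple[int, int]:
    n = coords.shape[0]
    if n <= 2000:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        return int(i), int(j)
    # double-sweep heuristic for big clouds
    i = 0
    for _ in range(2):
        d = np.linalg.norm(coords - coords[i], axis=1)
        j, i = i, int(np.argmax(d))
    return j, i


def leaf_length(
    leaf_cloud: PointCloud, r: float, step: float | None = None
) -> float:
    """Midrib path length (cm): greedy walk between the farthest point pair.

    From the start point, repeatedly move to the in-radius point whose
    step direction aligns best with the direction toward the end (among
    points that strictly reduce the distance to the end), accumulating
    Euclidean step lengths. If no in-radius point advances, the walk jumps
    to the nearest unvisited point strictly closer to the end. Always at
    least the straight base-tip distance.
    """
    coords = leaf_cloud.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n == 2:
        return float(np.linalg.norm(coords[0] - coords[1]) * r)
    coords = _denoise_if_thick(coords)
    start, end = _farthest_pair(coords)
    tree = cKDTree(coords)
    if step is None:
        # wide enough that many candidates fall in the forward cone, so the
        # best-aligned step is nearly straight and the path does not inflate
        nn_dist, _ = tree.query(coords, k=2)
        step = 8.0 * float(np.median(nn_dist[:, 1]))
    d_end = np.linalg.norm(coords - coords[end], axis=1)
    visited = np.zeros(n, dtype=bool)
    visited[start] = True
    cur, length = start, 0.0
    for _ in range(n):
        if cur == end:
            break
        cand = np.array(tree.query_ball_point(coords[cur], step), dtype=np.int64)
        cand = cand[~visited[cand]]
        cand = cand[d_end[cand] < d_end[cur] - 1e-12]
        if cand.size:
            steps = coords[cand] - coords[cur]
            norms = np.linalg.norm(steps, axis=1)
            to_end = coords[end] - coords[cur]
            align = steps @ to_end / (norms * np.linalg.norm(to_end) + 1e-300)
            nxt = int(cand[np.argmax(align)])
        else:
            closer = np.flatnonzero(~visited & (d_end < d_end[cur] - 1e-12))
            if closer.size == 0:
                length += d_end[cur]
                cur = end
                break
            steps = np.linalg.norm(coords[closer] - coords[cur], axis=1)
            nxt = int(closer[np.argmin(steps)])
        length += float(np.linalg.norm(coords[nxt] - coords[cur]))
        visited[nxt] = True
        cur = nxt
    if cur != end:
        length += d_end[cur]
    return float(length * r)


def leaf_width(
    leaf_cloud: PointCloud,
    r: float,
    mode: str = "leaf-frame",
    frame: PlantFrame | None = None,
) -> float:
    """Leaf width (cm): widest extent across the leaf.

    ``leaf-frame`` (default): extent along the leaf's own second principal
    axis, so the measurement is independent of the leaf's azimuth on the
    plant. ``global-x``: literal bounding-box X extent in the plant frame.
    """
    coords = leaf_cloud.coords
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if mode == "global-x":
        if frame is None:
            raise ValueError("global-x mode requires a PlantFrame")
        x = frame.apply(coords)[:, 0]
        return float((x.max() - x.min()) * r)
    if mode != "leaf-frame":
        raise ValueError(f"unknown width mode {mode!r}")
    coords = _denoise_if_thick(coords)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        warnings.warn("collinear leaf: width is 0", stacklevel=2)
        return 0.0
    t = centered @ vt[1]
    return float((t.max() - t.min()) * r)


def leaf_angle(petiole_cloud: PointCloud, frame: PlantFrame) -> float:
    """Angle (degrees) between the petiole direction and the stem axis.

    The petiole direction is its first principal component, oriented to
    point away from the stem axis (from the petiole end nearest the axis
    to the far end); the returned angle lies in [0, 180].
    """
    coords = petiole_cloud.coords
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 petiole points")
    pts = frame.apply(coords)
    b = _principal_axis(pts)
    proj = pts @ b
    # robust end comparison: mean distance from the stem (Z) axis over the
    # quartile of points at each projection extreme
    q1, q3 = np.quantile(proj, [0.25, 0.75])
    lo_r = np.linalg.norm(pts[proj <= q1, :2], axis=1).mean()
    hi_r = np.linalg.norm(pts[proj >= q3, :2], axis=1).mean()
    extent = float(proj.max() - proj.min())
    if abs(lo_r - hi_r) < 0.02 * extent:
        # near-vertical petiole: radially ambiguous, orient upward
        if b[2] < 0:
            b = -b
    elif lo_r > hi_r:
        b = -b
    angle = np.degrees(np.arccos(np.clip(b[2], -1.0, 1.0)))
    return float(angle)


def leaf_area(leaf_cloud: PointCloud, r: float) -> float:
    """Leaf area (cm^2) by Delaunay triangulation in the leaf's PCA plane.

    The cloud is projected onto its first two principal components,
    triangulated, and the 2D triangle areas are summed. Triangles whose
    circumradius exceeds 5x the median edge length are dropped so that
    the mesh does not bridge concave margins.
    """
    coords = leaf_cloud.coords
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    coords = _denoise_if_thick(coords)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("collinear leaf: area undefined")
    pts2d = centered @ vt[:2].T
    tri = Delaunay(pts2d)
    simplices = tri.simplices
    p = pts2d[simplices]  # (m, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    areas = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    edges = np.stack(
        [
            np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
            np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
            np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
        ],
        axis=1,
    )
    median_edge = float(np.median(edges))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = edges.prod(axis=1) / (4.0 * areas)
    keep = (areas > 0) & (circum <= 5.0 * median_edge)
    return float(areas[keep].sum() * r * r)


def associate_petioles(labeled: LabeledCloud) -> dict[int, PointCloud]:
    """Group petiole points by leaf instance.

    Petiole points already carrying an instance id are grouped directly;
    unassigned ones adopt the instance of the nearest labelled leaf point.
    """
    pet_mask = labeled.semantic == PETIOLE
    leaf_mask = (labeled.semantic == LEAF) & (labeled.instance >= 0)
    pet_idx = np.flatnonzero(pet_mask)
    if pet_idx.size == 0:
        return {}
    inst = labeled.instance[pet_idx].copy()
    unassigned = inst < 0
    if unassigned.any() and leaf_mask.any():
        tree = cKDTree(labeled.cloud.coords[leaf_mask])
        _, nearest = tree.query(labeled.cloud.coords[pet_idx[unassigned]])
        inst[unassigned] = labeled.instance[np.flatnonzero(leaf_mask)][nearest]
    out: dict[int, PointCloud] = {}
    for leaf_id in np.unique(inst[inst >= 0]):
        out[int(leaf_id)] = labeled.cloud.select(pet_idx[inst == leaf_id])
    return out


def extract_all_traits(
    labeled: LabeledCloud,
    petiole_map: dict[int, PointCloud] | None,
    r: float,
    min_leaf_points: int = 30,
    slice_height: float = 2.0,
    slab: float = 0.4,
    width_mode: str = "leaf-frame",
) -> TraitReport:
    """All six phenotypic parameters from a fully labelled plant cloud.

    The frame is calibrated from the stem; plant height and stem diameter
    are computed once, then length/width/angle/area per leaf instance.
    Instances below ``min_leaf_points`` or without an associated petiole
    are skipped with a recorded reason. The diameter slab is doubled (up
    to twice) if the default slice is too sparse to fit a circle.
    """
    stem = labeled.organ(STEM)
    if len(stem) == 0:
        raise ValueError("no stem points: cannot calibrate the plant frame")
    frame = calibrate_frame(stem)
    height = plant_height(labeled.cloud, frame, r)
    diameter = None
    last_err: Exception | None = None
    for trial_slab in (slab, 2 * slab, 4 * slab):
        try:
            diameter = stem_diameter(stem, frame, r, slice_height, trial_slab)
            break
        except ValueError as err:
            last_err = err
    if diameter is None:
        raise ValueError(f"stem diameter failed: {last_err}")
    if petiole_map is None:
        petiole_map = associate_petioles(labeled)
    leaves: list[LeafTraits] = []
    skipped: list[tuple[int, str]] = []
    leaf_mask = labeled.semantic == LEAF
    ids = np.unique(labeled.instance[leaf_mask & (labeled.instance >= 0)])
    for leaf_id in ids:
        sub = labeled.cloud.select(leaf_mask & (labeled.instance == leaf_id))
        if len(sub) < min_leaf_points:
            skipped.append((int(leaf_id), f"only {len(sub)} points"))
            continue
        petiole = petiole_map.get(int(leaf_id))
        if petiole is None or len(petiole) < 3:
            skipped.append((int(leaf_id), "no associated petiole"))
            continue
        try:
            leaves.append(
                LeafTraits(
                    instance_id=int(leaf_id),
                    length_cm=leaf_length(sub, r),
                    width_cm=leaf_width(sub, r, mode=width_mode, frame=frame),
                    angle_deg=leaf_angle(petiole, frame),
                    area_cm2=leaf_area(sub, r),
                )
            )
        except ValueError as err:
            skipped.append((int(leaf_id), str(err)))
    return TraitReport(height, diameter, leaves, skipped)
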