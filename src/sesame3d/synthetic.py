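"""Seeded parametric generator of sesame-like plant scenes.

The generator emulates what a multi-view reconstruction of a potted sesame
plant looks like after dense matching: a near-vertical tapered stem,
petioles branching off at known angles, lanceolate leaf laminae (half-width
profile ``h(t) = (W/2) sin(pi t)^0.8`` along the midrib), brown soil, a
calibration cube of known edge length, and additive coordinate noise.

Every surface is parametric, so the ground-truth traits are computed by
dense quadrature on the parametric forms — never from the sampled points —
keeping the generator an independent oracle for the trait extractors.

Units: one generator unit corresponds to ``2 / cube_edge`` centimetres
(the calibration cube is 2 cm in the real world). With the default cube
edge of 0.05 units, r = 40 cm/unit and the default plant stands ~1 m tall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import LEAF, PETIOLE, STEM, LabeledCloud, PointCloud

CUBE_REAL_EDGE_CM = 2.0

# base RGB per scene component; jitter of +-10 keeps the plant strictly
# above and the background strictly below the ExG = 30 vegetation threshold
STEM_RGB = (90, 150, 70)
PETIOLE_RGB = (85, 145, 65)
LEAF_RGB = (55, 135, 55)
SOIL_RGB = (140, 85, 50)
CUBE_RGB = (120, 110, 140)


@dataclass
class StemSpec:
    height: float = 2.5              # units (~1 m at r = 40)
    base_radius: float = 0.012       # units (~9.6 mm diameter)
    taper: float = 0.3               # tip radius = base_radius * (1 - taper)
    bow: float = 0.0                 # lateral tip displacement, units


@dataclass
class LeafSpec:
    attach_height: float             # fraction of stem height
    azimuth_deg: float               # [0, 360)
    petiole_length: float = 0.15     # units
    petiole_angle_deg: float = 50.0  # from the stem axis, [0, 180]
    lamina_length: float = 0.25      # midrib length, units
    lamina_width: float = 0.12       # maximal full width, units
    droop_deg: float = 15.0          # downward bend of the midrib tip
    petiole_radius: float = 0.004    # units


@dataclass
class SoilSpec:
    radius: float = 0.9              # units
    density: float = 4000.0          # points per unit^2
    rgb: tuple[int, int, int] = SOIL_RGB


@dataclass
class CubeSpec:
    edge: float = 0.05               # units; implies r = 2 / edge cm/unit
    center_xy: tuple[float, float] = (0.6, 0.0)
    density: float = 30000.0         # points per unit^2 of face area
    rgb: tuple[int, int, int] = CUBE_RGB


@dataclass
class SyntheticPlantSpec:
    """Full description of one synthetic plant scene.

    Densities are points per unit^2 of surface area. The lamina density
    default is chosen so the density-clustering operating point
    (eps = 0.006, min_pts = 10) sits in its good regime: the expected
    eps-neighborhood then holds ~28 points, comfortably above min_pts.
    """

    seed: int = 0
    stem: StemSpec = field(default_factory=StemSpec)
    leaves: list[LeafSpec] = field(default_factory=list)
    # multi-view reconstructions sample every surface at a similar density,
    # so all plant organs share one default; keeping them equal also keeps
    # statistical outlier removal from preferentially eroding sparser organs
    lamina_density: float = 250000.0
    petiole_density: float = 250000.0
    stem_density: float = 250000.0
    noise_sigma: float = 0.0         # additive isotropic Gaussian, units
    rgb_jitter: int = 10
    soil: SoilSpec = field(default_factory=SoilSpec)
    cube: CubeSpec = field(default_factory=CubeSpec)

    def __post_init__(self) -> None:
        if self.stem.height <= 0 or self.stem.base_radius <= 0:
            raise ValueError("stem dimensions must be positive")
        for leaf in self.leaves:
            if not 0 < leaf.attach_height < 1:
                raise ValueError("attach_height must be a fraction in (0, 1)")
            if not 0 <= leaf.petiole_angle_deg <= 180:
                raise ValueError("petiole angle must lie in [0, 180]")
            if leaf.lamina_length <= 0 or leaf.lamina_width <= 0:
                raise ValueError("lamina dimensions must be positive")

    @property
    def r(self) -> float:
        """Implied scale factor, cm per unit."""
        return CUBE_REAL_EDGE_CM / self.cube.edge


@dataclass
class LeafTruth:
    instance_id: int
    length_cm: float
    width_cm: float
    angle_deg: float
    area_cm2: float


@dataclass
class GroundTruth:
    """Analytic trait values implied by a :class:`SyntheticPlantSpec`."""

    r: float
    plant_height_cm: float
    stem_diameter_mm: float
    leaves: list[LeafTruth]
    contact_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )


@dataclass
class SceneInfo:
    """Index ranges of the components inside a merged scene cloud."""

    plant: slice
    soil: slice
    cube: slice


def default_plant_spec(seed: int = 0, n_leaves: int = 6) -> SyntheticPlantSpec:
    """The standard plant: evenly spread leaves on a golden-angle spiral."""
    leaves = [
        LeafSpec(
            attach_height=0.30 + 0.55 * i / max(n_leaves - 1, 1),
            azimuth_deg=(i * 137.5) % 360.0,
        )
        for i in range(n_leaves)
    ]
    return SyntheticPlantSpec(seed=seed, leaves=leaves)


def random_plant_spec(
    seed: int, n_leaves: int = 6, density_scale: float = 1.0
) -> SyntheticPlantSpec:
    """A plant with trait values drawn from realistic sesame ranges.

    Heights span 0.8-1.2 m, stem diameters 8-18 mm, leaf lengths 7-13 cm,
    widths 45-60 % of length, petiole angles 25-75 degrees (at r = 40).
    """
    rng = np.random.default_rng(seed)
    stem = StemSpec(
        height=float(rng.uniform(2.0, 3.0)),
        base_radius=float(rng.uniform(0.010, 0.022)),
        taper=float(rng.uniform(0.2, 0.4)),
    )
    attach = np.sort(rng.uniform(0.30, 0.85, size=n_leaves))
    leaves = []
    for i in range(n_leaves):
        length = float(rng.uniform(0.18, 0.32))
        leaves.append(
            LeafSpec(
                attach_height=float(attach[i]),
                azimuth_deg=float((i * 137.5 + rng.uniform(-20, 20)) % 360),
                petiole_length=float(rng.uniform(0.10, 0.18)),
                petiole_angle_deg=float(rng.uniform(25.0, 75.0)),
                lamina_length=length,
                lamina_width=float(length * rng.uniform(0.45, 0.60)),
                droop_deg=float(rng.uniform(5.0, 25.0)),
            )
        )
    spec = SyntheticPlantSpec(seed=seed, stem=stem, leaves=leaves)
    if density_scale != 1.0:
        spec = replace(
            spec,
            lamina_density=spec.lamina_density * density_scale,
            petiole_density=spec.petiole_density * density_scale,
            stem_density=spec.stem_density * density_scale,
        )
    return spec


# ---------------------------------------------------------------------------
# parametric forms


def _half_width(t: np.ndarray, width: float) -> np.ndarray:
    return 0.5 * width * np.sin(np.pi * np.clip(t, 0.0, 1.0)) ** 0.8


def _stem_centerline(spec: StemSpec, t: np.ndarray) -> np.ndarray:
    return np.stack(
        [spec.bow * t**2, np.zeros_like(t), spec.height * t], axis=-1
    )


def _stem_radius(spec: StemSpec, t: np.ndarray) -> np.ndarray:
    return spec.base_radius * (1.0 - spec.taper * t)


def _midrib(leaf: LeafSpec, stem: StemSpec, t: np.ndarray):
    """Midrib points and unit cross direction for a regular leaf.

    The midrib starts at the petiole tip and bends downward linearly in
    elevation by ``droop_deg`` over its length (unit-speed curve, so the
    midrib arc length equals ``lamina_length`` exactly).
    """
    phi = np.radians(leaf.azimuth_deg)
    beta0 = np.radians(90.0 - leaf.petiole_angle_deg)
    droop = np.radians(leaf.droop_deg)
    attach = _stem_centerline(stem, np.asarray(leaf.attach_height))
    d = np.array(
        [np.cos(beta0) * np.cos(phi), np.cos(beta0) * np.sin(phi), np.sin(beta0)]
    )
    tip0 = attach + leaf.petiole_length * d
    beta = beta0 - droop * t
    if droop < 1e-12:
        arc_h = t * np.cos(beta0)
        arc_z = t * np.sin(beta0)
    else:
        arc_h = (np.sin(beta0) - np.sin(beta)) / droop
        arc_z = (np.cos(beta) - np.cos(beta0)) / droop
    pts = tip0 + leaf.lamina_length * np.stack(
        [arc_h * np.cos(phi), arc_h * np.sin(phi), arc_z], axis=-1
    )
    u = np.array([-np.sin(phi), np.cos(phi), 0.0])  # horizontal cross direction
    return pts, u


def _lamina_surface(leaf: LeafSpec, stem: StemSpec, t: np.ndarray, v: np.ndarray):
    """Points of the ruled lamina surface s(t, v) = m(t) + v h(t) u."""
    m, u = _midrib(leaf, stem, t)
    h = _half_width(t, leaf.lamina_width)
    return m + (v * h)[:, None] * u


def _lamina_area_quadrature(leaf: LeafSpec, n: int = 2000) -> float:
    """Surface area by quadrature: |s_t x s_v| = L * h(t) for this surface."""
    t = (np.arange(n) + 0.5) / n
    h = _half_width(t, leaf.lamina_width)
    return float(2.0 * leaf.lamina_length * h.mean())


def _sample_t_by_width(rng, leaf: LeafSpec, n: int) -> np.ndarray:
    """Draw midrib parameters with density proportional to the local width."""
    grid = np.linspace(0.0, 1.0, 4097)
    w = _half_width(grid, leaf.lamina_width)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _sample_cylinder(rng, p0, p1, radius0, radius1, density) -> np.ndarray:
    """Uniform-ish samples on a (tapered) open cylinder between p0 and p1."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / length
    mean_r = 0.5 * (radius0 + radius1)
    n = max(int(round(2 * np.pi * mean_r * length * density)), 24)
    t = rng.random(n)
    theta = rng.uniform(0, 2 * np.pi, n)
    radius = radius0 + (radius1 - radius0) * t
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    return (
        p0
        + t[:, None] * (length * axis)
        + (radius * np.cos(theta))[:, None] * u
        + (radius * np.sin(theta))[:, None] * w
    )


# ---------------------------------------------------------------------------
# generation


def _plant_truth(spec: SyntheticPlantSpec, lamina_points: list[np.ndarray]) -> GroundTruth:
    r = spec.r
    # height: extreme Z difference over the parametric parts evaluated densely
    t = np.linspace(0.0, 1.0, 2001)
    z_min, z_max = 0.0, spec.stem.height
    for leaf in spec.leaves:
        m, _ = _midrib(leaf, spec.stem, t)
        z_min = min(z_min, float(m[:, 2].min()))
        z_max = max(z_max, float(m[:, 2].max()))
    height_cm = (z_max - z_min) * r
    z_slice = 2.0 / r  # the 2 cm measurement height in units
    t_slice = np.clip(z_slice / spec.stem.height, 0.0, 1.0)
    diameter_mm = float(2.0 * _stem_radius(spec.stem, t_slice) * r * 10.0)
    leaves = [
        LeafTruth(
            instance_id=i,
            length_cm=leaf.lamina_length * r,
            width_cm=leaf.lamina_width * r,
            angle_deg=leaf.petiole_angle_deg,
            area_cm2=_lamina_area_quadrature(leaf) * r * r,
        )
        for i, leaf in enumerate(spec.leaves)
    ]
    return GroundTruth(r, height_cm, diameter_mm, leaves)


def generate_plant(
    spec: SyntheticPlantSpec,
) -> tuple[LabeledCloud, GroundTruth]:
    """Sample a labelled plant cloud and its analytic ground truth.

    Deterministic given ``spec.seed``. Semantic labels: 0 stem, 1 petiole,
    2 leaf; instance ids number the leaves (petiole points carry the id of
    their leaf).
    """
    rng = np.random.default_rng([spec.seed, 0])
    coords_parts, colors_parts, semantic, instance = [], [], [], []

    # stem
    stem = spec.stem
    area = 2 * np.pi * stem.base_radius * (1 - stem.taper / 2) * stem.height
    n_stem = max(int(round(area * spec.stem_density)), 200)
    t = rng.random(n_stem)
    theta = rng.uniform(0, 2 * np.pi, n_stem)
    center = _stem_centerline(stem, t)
    radius = _stem_radius(stem, t)
    pts = center + np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_stem)], axis=-1
    )
    coords_parts.append(pts)
    semantic.append(np.full(n_stem, STEM))
    instance.append(np.full(n_stem, -1))
    colors_parts.append(np.tile(STEM_RGB, (n_stem, 1)))

    lamina_points: list[np.ndarray] = []
    for i, leaf in enumerate(spec.leaves):
        phi = np.radians(leaf.azimuth_deg)
        beta0 = np.radians(90.0 - leaf.petiole_angle_deg)
        attach = _stem_centerline(stem, np.asarray(leaf.attach_height))
        d = np.array(
            [np.cos(beta0) * np.cos(phi), np.cos(beta0) * np.sin(phi), np.sin(beta0)]
        )
        tip = attach + leaf.petiole_length * d
        pet = _sample_cylinder(
            rng, attach, tip, leaf.petiole_radius, leaf.petiole_radius,
            spec.petiole_density,
        )
        coords_parts.append(pet)
        semantic.append(np.full(pet.shape[0], PETIOLE))
        instance.append(np.full(pet.shape[0], i))
        colors_parts.append(np.tile(PETIOLE_RGB, (pet.shape[0], 1)))

        n_lam = max(int(round(_lamina_area_quadrature(leaf) * spec.lamina_density)), 60)
        t_lam = _sample_t_by_width(rng, leaf, n_lam)
        v_lam = rng.uniform(-1.0, 1.0, n_lam)
        lam = _lamina_surface(leaf, stem, t_lam, v_lam)
        lamina_points.append(lam)
        coords_parts.append(lam)
        semantic.append(np.full(n_lam, LEAF))
        instance.append(np.full(n_lam, i))
        colors_parts.append(np.tile(LEAF_RGB, (n_lam, 1)))

    coords = np.concatenate(coords_parts, axis=0)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    colors = np.concatenate(colors_parts, axis=0).astype(np.int64)
    if spec.rgb_jitter:
        colors = colors + rng.integers(
            -spec.rgb_jitter, spec.rgb_jitter + 1, colors.shape
        )
    colors = np.clip(colors, 0, 255).astype(np.uint8)
    labeled = LabeledCloud(
        PointCloud(coords, colors),
        np.concatenate(semantic),
        np.concatenate(instance),
    )
    return labeled, _plant_truth(spec, lamina_points)


def generate_scene(
    labeled: LabeledCloud, spec: SyntheticPlantSpec
) -> tuple[PointCloud, SceneInfo]:
    """Merge a plant with a soil disk and the calibration cube.

    Scene order is plant, soil, cube; the returned :class:`SceneInfo`
    records each component's index range so construction-side guarantees
    (e.g. which points pass the ExG filter) can be checked exactly.
    """
    rng = np.random.default_rng([spec.seed, 1])
    plant_coords = labeled.cloud.coords
    plant_colors = (
        labeled.cloud.colors
        if labeled.cloud.has_colors
        else np.tile(LEAF_RGB, (len(labeled), 1))
    )

    n_soil = max(int(round(np.pi * spec.soil.radius**2 * spec.soil.density)), 100)
    rho = spec.soil.radius * np.sqrt(rng.random(n_soil))
    phi = rng.uniform(0, 2 * np.pi, n_soil)
    soil = np.stack(
        [rho * np.cos(phi), rho * np.sin(phi), rng.normal(0, 0.002, n_soil)], axis=-1
    )

    edge = spec.cube.edge
    n_cube = max(int(round(6 * edge**2 * spec.cube.density)), 300)
    face = rng.integers(0, 6, n_cube)
    uv = rng.random((n_cube, 2)) * edge
    cube = np.zeros((n_cube, 3))
    axis_of_face = face // 2
    offset = (face % 2).astype(float) * edge
    for a in range(3):
        m = axis_of_face == a
        others = [x for x in range(3) if x != a]
        cube[m, a] = offset[m]
        cube[m, others[0]] = uv[m, 0]
        cube[m, others[1]] = uv[m, 1]
    cube[:, 0] += spec.cube.center_xy[0] - edge / 2
    cube[:, 1] += spec.cube.center_xy[1] - edge / 2

    coords = np.concatenate([plant_coords, soil, cube], axis=0)
    if spec.noise_sigma > 0:
        extra = rng.normal(0.0, spec.noise_sigma, (n_soil + n_cube, 3))
        coords[len(labeled):] += extra
    base_colors = np.concatenate(
        [
            plant_colors.astype(np.int64),
            np.tile(spec.soil.rgb, (n_soil, 1)),
            np.tile(spec.cube.rgb, (n_cube, 1)),
        ]
    )
    if spec.rgb_jitter:
        # the plant already got its jitter in generate_plant
        base_colors[len(labeled):] += rng.integers(
            -spec.rgb_jitter, spec.rgb_jitter + 1, (n_soil + n_cube, 3)
        )
    colors = np.clip(base_colors, 0, 255).astype(np.uint8)
    n_plant = len(labeled)
    info = SceneInfo(
        plant=slice(0, n_plant),
        soil=slice(n_plant, n_plant + n_soil),
        cube=slice(n_plant + n_soil, n_plant + n_soil + n_cube),
    )
    return PointCloud(coords, colors), info


def make_adhesion_case(
    spec: SyntheticPlantSpec,
    contact_pairs: list[tuple[int, int]],
    fold_half_angle_deg: float = 30.0,
    contact_width: float = 0.012,
    contact_jitter: float = 0.003,
) -> tuple[LabeledCloud, GroundTruth]:
    """A plant in which given leaf pairs touch along a shared contact line.

    Each listed pair is rebuilt as an "open book": the two laminae share a
    straight spine and open at a dihedral of ``180 - 2*fold_half_angle``
    degrees. Points within ``contact_width`` of the spine are additionally
    jittered across the surface (emulating the interleaved, disordered
    points of a real adhesion area) and flagged in
    ``GroundTruth.contact_indices``.
    """
    n_leaves = len(spec.leaves)
    if any(i >= n_leaves or j >= n_leaves for i, j in contact_pairs):
        raise ValueError("contact pair references a leaf that does not exist")
    if len({k for pair in contact_pairs for k in pair}) < 2 * len(contact_pairs):
        raise ValueError("a leaf may appear in at most one contact pair")
    if not contact_pairs:
        return generate_plant(spec)

    paired = {k for pair in contact_pairs for k in pair}
    base_spec = replace(
        spec, leaves=[l for k, l in enumerate(spec.leaves) if k not in paired]
    )
    labeled, _ = generate_plant(base_spec)
    # remap instance ids of the untouched leaves back to their original ids
    free_ids = [k for k in range(n_leaves) if k not in paired]
    remap = {new: orig for new, orig in enumerate(free_ids)}
    instance = np.array(
        [remap.get(v, -1) if v >= 0 else -1 for v in labeled.instance], dtype=np.int64
    )

    rng = np.random.default_rng([spec.seed, 2])
    psi = np.radians(fold_half_angle_deg)
    coords = [labeled.cloud.coords]
    colors = [labeled.cloud.colors.astype(np.int64)]
    semantic = [labeled.semantic]
    instances = [instance]
    contact_flags = [np.zeros(len(labeled), dtype=bool)]

    stem = spec.stem
    truth_leaves: dict[int, LeafTruth] = {}
    for i, j in contact_pairs:
        li, lj = spec.leaves[i], spec.leaves[j]
        attach_h = 0.5 * (li.attach_height + lj.attach_height)
        phi = np.radians(li.azimuth_deg)
        beta0 = np.radians(90.0 - li.petiole_angle_deg)
        attach = _stem_centerline(stem, np.asarray(attach_h))
        e = np.array(
            [np.cos(beta0) * np.cos(phi), np.cos(beta0) * np.sin(phi), np.sin(beta0)]
        )
        spine0 = attach + li.petiole_length * e
        u0 = np.array([-np.sin(phi), np.cos(phi), 0.0])
        n0 = np.cross(e, u0)
        u_side = {
            i: np.cos(psi) * u0 + np.sin(psi) * n0,
            j: -(np.cos(psi) * u0 - np.sin(psi) * n0),
        }
        length, width = li.lamina_length, li.lamina_width
        for leaf_id in (i, j):
            pet = _sample_cylinder(
                rng, attach, spine0, li.petiole_radius, li.petiole_radius,
                spec.petiole_density,
            )
            coords.append(pet)
            colors.append(np.tile(PETIOLE_RGB, (pet.shape[0], 1)))
            semantic.append(np.full(pet.shape[0], PETIOLE))
            instances.append(np.full(pet.shape[0], leaf_id))
            contact_flags.append(np.zeros(pet.shape[0], dtype=bool))

            proto = LeafSpec(
                attach_height=attach_h,
                azimuth_deg=li.azimuth_deg,
                petiole_length=li.petiole_length,
                petiole_angle_deg=li.petiole_angle_deg,
                lamina_length=length,
                lamina_width=width,
            )
            n_lam = max(
                int(round(_lamina_area_quadrature(proto) * spec.lamina_density)), 60
            )
            t = _sample_t_by_width(rng, proto, n_lam)
            v = rng.random(n_lam)  # [0, 1]: distance fraction from the spine
            h = _half_width(t, width)
            u = u_side[leaf_id]
            lam = spine0 + (t * length)[:, None] * e + (2 * v * h)[:, None] * u
            dist_to_spine = 2 * v * h
            in_contact = dist_to_spine < contact_width
            normal = np.cross(e, u)
            lam[in_contact] += (
                rng.normal(0.0, contact_jitter, int(in_contact.sum()))[:, None]
                * normal
            )
            coords.append(lam)
            colors.append(np.tile(LEAF_RGB, (n_lam, 1)))
            semantic.append(np.full(n_lam, LEAF))
            instances.append(np.full(n_lam, leaf_id))
            contact_flags.append(in_contact)

            grid = np.linspace(1e-6, 1 - 1e-6, 4001)
            hg = _half_width(grid, width)
            dh = np.gradient(hg, grid)
            midrib_len = float(
                np.trapezoid(np.sqrt(length**2 + dh**2), grid)
            )
            truth_leaves[leaf_id] = LeafTruth(
                instance_id=leaf_id,
                length_cm=midrib_len * spec.r,
                width_cm=width * spec.r,
                angle_deg=li.petiole_angle_deg,
                area_cm2=_lamina_area_quadrature(proto) * spec.r**2,
            )

    all_coords = np.concatenate(coords, axis=0)
    if spec.noise_sigma > 0:
        all_coords = all_coords + rng.normal(0.0, spec.noise_sigma, all_coords.shape)
    all_colors = np.concatenate(colors, axis=0)
    if spec.rgb_jitter:
        new_part = slice(len(labeled), all_colors.shape[0])
        all_colors[new_part] += rng.integers(
            -spec.rgb_jitter, spec.rgb_jitter + 1,
            (all_colors.shape[0] - len(labeled), 3),
        )
    all_colors = np.clip(all_colors, 0, 255).astype(np.uint8)
    out = LabeledCloud(
        PointCloud(all_coords, all_colors),
        np.concatenate(semantic),
        np.concatenate(instances),
    )

    base_truth = _plant_truth(spec, [])
    leaves = [
        truth_leaves.get(
            k,
            next(
                (
                    LeafTruth(k, l.length_cm, l.width_cm, l.angle_deg, l.area_cm2)
                    for l in base_truth.leaves
                    if l.instance_id == k
                ),
                None,
            ),
        )
        for k in range(n_leaves)
    ]
    # recompute per-leaf truth for free leaves against the reduced spec ids
    free_truth = {
        remap[new]: LeafTruth(
            remap[new], l.length_cm, l.width_cm, l.angle_deg, l.area_cm2
        )
        for new, l in enumerate(_plant_truth(base_spec, []).leaves)
    }
    leaves = [
        truth_leaves.get(k, free_truth.get(k))
        for k in range(n_leaves)
    ]
    truth = GroundTruth(
        r=spec.r,
        plant_height_cm=base_truth.plant_height_cm,
        stem_diameter_mm=base_truth.stem_diameter_mm,
        leaves=[l for l in leaves if l is not None],
        contact_indices=np.flatnonzero(np.concatenate(contact_flags)),
    )
    return out, truth
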