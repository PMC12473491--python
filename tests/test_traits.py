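import numpy as np
import pytest

from sesame3d import (
    PointCloud,
    calibrate_frame,
    extract_all_traits,
    fit_circle,
    leaf_angle,
    leaf_area,
    leaf_length,
    leaf_width,
    plant_height,
    stem_diameter,
)


def stem_line(direction, length=10.0, n=300, radius=0.05, seed=0):
    rng = np.random.default_rng(seed)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    t = np.linspace(0, length, n)
    ref = np.array([1.0, 0, 0]) if abs(direction[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    w = np.cross(direction, u)
    theta = rng.uniform(0, 2 * np.pi, n)
    return PointCloud(
        t[:, None] * direction
        + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * w)
    )


class TestFrameCalibration:
    def test_vertical_stem_gives_identity_rotation(self):
        frame = calibrate_frame(stem_line([0, 0, 1]))
        np.testing.assert_allclose(np.abs(frame.stem_axis[2]), 1.0, atol=1e-3)
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0)

    def test_oblique_stem_z_extent_equals_length(self):
        length = 7.0
        stem = stem_line([1, 1, 1], length=length, radius=1e-6)
        frame = calibrate_frame(stem)
        z = frame.apply(stem.coords)[:, 2]
        assert z.max() - z.min() == pytest.approx(length, rel=1e-4)
        assert z.min() == pytest.approx(0.0, abs=1e-6)

    def test_z_variance_is_maximal_after_transform(self):
        stem = stem_line([0.3, -0.5, 1.0])
        pts = calibrate_frame(stem).apply(stem.coords)
        var = pts.var(axis=0)
        assert var[2] >= var[0] and var[2] >= var[1]

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            calibrate_frame(PointCloud(np.zeros((2, 3))))


class TestPlantHeight:
    def test_z_extent_times_scale(self):
        stem = stem_line([0, 0, 1], length=10, radius=1e-6)
        frame = calibrate_frame(stem)
        assert plant_height(stem, frame, 1.0) == pytest.approx(10.0, rel=1e-4)
        assert plant_height(stem, frame, 2.0) == pytest.approx(20.0, rel=1e-4)


class TestFitCircle:
    def test_exact_circle(self):
        pts = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        center, radius = fit_circle(pts)
        np.testing.assert_allclose(center, [0, 0], atol=1e-12)
        assert radius == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_three_points_give_circumcircle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 2))
        a, b, c = (np.linalg.norm(pts[i] - pts[j]) for i, j in ((1, 2), (0, 2), (0, 1)))
        s = (a + b + c) / 2
        area = np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0))
        expected = a * b * c / (4 * area)
        _, radius = fit_circle(pts)
        assert radius == pytest.approx(expected, rel=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        theta = rng.uniform(0, 2 * np.pi, 40)
        pts = np.stack([2 * np.cos(theta), 2 * np.sin(theta)], 1)
        c1, r1 = fit_circle(pts)
        c2, r2 = fit_circle(pts + [5, -3])
        np.testing.assert_allclose(c2, c1 + [5, -3], atol=1e-9)
        assert r2 == pytest.approx(r1)

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            fit_circle(np.array([[0.0, 0], [1, 0], [2, 0]]))


class TestStemDiameter:
    def test_cylinder_diameter_10mm(self):
        # cylinder radius 0.0125 units with r = 40 -> real radius 0.5 cm
        stem = stem_line([0, 0, 1], length=0.2, n=4000, radius=0.0125, seed=1)
        frame = calibrate_frame(stem)
        d = stem_diameter(stem, frame, r=40.0, slice_height=2.0, slab=0.4)
        assert d == pytest.approx(10.0, rel=0.02)

    def test_doubling_slab_on_cylinder_changes_nothing(self):
        stem = stem_line([0, 0, 1], length=0.2, n=4000, radius=0.0125, seed=2)
        frame = calibrate_frame(stem)
        d1 = stem_diameter(stem, frame, 40.0, slab=0.4)
        d2 = stem_diameter(stem, frame, 40.0, slab=0.8)
        assert d2 == pytest.approx(d1, rel=0.01)

    def test_empty_slab_raises_with_hint(self):
        stem = stem_line([0, 0, 1], length=0.01, n=100, radius=0.001)
        frame = calibrate_frame(stem)
        with pytest.raises(ValueError, match="slab"):
            stem_diameter(stem, frame, r=1.0, slice_height=50.0, slab=0.1)


class TestLeafLength:
    def test_straight_dense_line(self):
        x = np.linspace(0, 1, 500)
        rng = np.random.default_rng(1)
        pts = np.stack([x, np.zeros_like(x), np.zeros_like(x)], 1)
        pts += rng.normal(0, 1e-5, pts.shape)
        assert leaf_length(PointCloud(pts), 1.0) == pytest.approx(1.0, rel=0.01)

    def test_semicircular_strip_recovers_arc_length(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, np.pi, 3000)
        w = rng.uniform(-0.01, 0.01, 3000)
        pts = np.stack(
            [(1 + w) * np.cos(theta), (1 + w) * np.sin(theta), np.zeros(3000)], 1
        )
        est = leaf_length(PointCloud(pts), 1.0)
        assert est == pytest.approx(np.pi, rel=0.05)
        assert est > 2.0  # clearly more than the chord

    def test_two_points_give_distance(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1]])
        assert leaf_length(PointCloud(pts), 2.0) == pytest.approx(2 * np.sqrt(3))

    def test_at_least_base_tip_distance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (500, 3)) * [1, 0.2, 0.02]
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2).max()
        assert leaf_length(PointCloud(pts), 1.0) >= d - 1e-9


class TestLeafWidth:
    def test_flat_ellipse_minor_axis(self):
        rng = np.random.default_rng(4)
        u, th = rng.random(4000), rng.uniform(0, 2 * np.pi, 4000)
        a, b = 2.0, 0.8
        pts = np.stack(
            [a * np.sqrt(u) * np.cos(th), b * np.sqrt(u) * np.sin(th), np.zeros(4000)], 1
        )
        assert leaf_width(PointCloud(pts), 1.0) == pytest.approx(2 * b, rel=0.02)

    def test_circle_both_modes(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(0, 2 * np.pi, 2000)
        u = np.sqrt(rng.random(2000))
        pts = np.stack([u * np.cos(th), u * np.sin(th), np.zeros(2000)], 1)
        cloud = PointCloud(pts)
        assert leaf_width(cloud, 1.0) == pytest.approx(2.0, rel=0.02)
        frame = calibrate_frame(stem_line([0, 0, 1]))
        assert leaf_width(cloud, 1.0, mode="global-x", frame=frame) == pytest.approx(
            2.0, rel=0.02
        )

    def test_rigid_rotation_invariance_leaf_frame(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1, (500, 3)) * [2, 0.5, 0.01]
        w1 = leaf_width(PointCloud(pts), 1.0)
        ang = 1.1
        rot = np.array(
            [[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]]
        )
        w2 = leaf_width(PointCloud(pts @ rot.T), 1.0)
        assert w2 == pytest.approx(w1, rel=1e-6)

    def test_collinear_leaf_warns_and_returns_zero(self):
        pts = np.stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)], 1)
        with pytest.warns(UserWarning):
            assert leaf_width(PointCloud(pts), 1.0) == 0.0


class TestLeafAngle:
    @pytest.mark.parametrize(
        "direction,expected",
        [((1, 0, 1), 45.0), ((0, 0, 1), 0.0), ((1, 0, 0), 90.0)],
    )
    def test_analytic_directions(self, direction, expected):
        frame = calibrate_frame(stem_line([0, 0, 1], radius=1e-6))
        direction = np.asarray(direction, float) / np.linalg.norm(direction)
        t = np.linspace(0.05, 1, 200)
        # petiole starting just off the stem axis, pointing outward
        pts = np.array([0.001, 0, 0.5]) + t[:, None] * direction
        rng = np.random.default_rng(7)
        pts = pts + rng.normal(0, 1e-5, pts.shape)
        assert leaf_angle(PointCloud(pts), frame) == pytest.approx(expected, abs=1.0)

    def test_degenerate_petiole_raises(self):
        frame = calibrate_frame(stem_line([0, 0, 1]))
        with pytest.raises(ValueError):
            leaf_angle(PointCloud(np.zeros((2, 3))), frame)


class TestLeafArea:
    def test_unit_square_with_center(self):
        pts = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.5, 0.5, 0]]
        )
        assert leaf_area(PointCloud(pts), 1.0) == pytest.approx(1.0)

    def test_side_two_square_area_four(self):
        pts = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        assert leaf_area(PointCloud(pts), 1.0) == pytest.approx(4.0)

    def test_scale_factor_enters_squared(self):
        pts = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        assert leaf_area(PointCloud(pts), 3.0) == pytest.approx(36.0)

    def test_dense_ellipse_area(self):
        rng = np.random.default_rng(8)
        u, th = rng.random(6000), rng.uniform(0, 2 * np.pi, 6000)
        a, b = 1.5, 0.7
        pts = np.stack(
            [a * np.sqrt(u) * np.cos(th), b * np.sqrt(u) * np.sin(th), np.zeros(6000)], 1
        )
        assert leaf_area(PointCloud(pts), 1.0) == pytest.approx(np.pi * a * b, rel=0.03)

    def test_collinear_raises(self):
        pts = np.stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)], 1)
        with pytest.raises(ValueError):
            leaf_area(PointCloud(pts), 1.0)


class TestRigidAndScaleInvariance:
    def test_scale_equivariance_of_all_traits(self, default_plant):
        spec, labeled, truth = default_plant
        r = truth.r
        rep1 = extract_all_traits(labeled, None, r)
        # scale coordinates by s, scale factor by 1/s: outputs identical
        s_factor = 2.5
        from sesame3d import LabeledCloud, PointCloud as PC

        scaled = LabeledCloud(
            PC(labeled.cloud.coords * s_factor, labeled.cloud.colors),
            labeled.semantic,
            labeled.instance,
        )
        rep2 = extract_all_traits(scaled, None, r / s_factor)
        assert rep2.plant_height_cm == pytest.approx(rep1.plant_height_cm, rel=1e-6)
        assert rep2.stem_diameter_mm == pytest.approx(rep1.stem_diameter_mm, rel=1e-6)
        for a, b in zip(rep1.leaves, rep2.leaves):
            assert b.length_cm == pytest.approx(a.length_cm, rel=1e-6)
            assert b.area_cm2 == pytest.approx(a.area_cm2, rel=1e-6)

    def test_rigid_motion_invariance(self, default_plant):
        spec, labeled, truth = default_plant
        rep1 = extract_all_traits(labeled, None, truth.r)
        ang = 0.6
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        ) @ np.array(
            [[np.cos(0.3), 0, np.sin(0.3)], [0, 1, 0], [-np.sin(0.3), 0, np.cos(0.3)]]
        )
        from sesame3d import LabeledCloud, PointCloud as PC

        moved = LabeledCloud(
            PC(labeled.cloud.coords @ rot.T + [3, -2, 5], labeled.cloud.colors),
            labeled.semantic,
            labeled.instance,
        )
        rep2 = extract_all_traits(moved, None, truth.r)
        assert rep2.plant_height_cm == pytest.approx(rep1.plant_height_cm, rel=1e-3)
        assert rep2.stem_diameter_mm == pytest.approx(rep1.stem_diameter_mm, rel=1e-2)
        for a, b in zip(rep1.leaves, rep2.leaves):
            assert b.angle_deg == pytest.approx(a.angle_deg, abs=0.5)


class TestExtractAllTraits:
    def test_noiseless_plant_recovers_all_six_traits(self, default_plant):
        spec, labeled, truth = default_plant
        rep = extract_all_traits(labeled, None, truth.r)
        assert rep.plant_height_cm == pytest.approx(truth.plant_height_cm, rel=0.02)
        assert rep.stem_diameter_mm == pytest.approx(truth.stem_diameter_mm, rel=0.02)
        by_id = {g.instance_id: g for g in truth.leaves}
        assert len(rep.leaves) == len(truth.leaves)
        for leaf in rep.leaves:
            g = by_id[leaf.instance_id]
            assert leaf.length_cm == pytest.approx(g.length_cm, rel=0.02)
            assert leaf.width_cm == pytest.approx(g.width_cm, rel=0.02)
            assert leaf.angle_deg == pytest.approx(g.angle_deg, abs=1.0)
            assert leaf.area_cm2 == pytest.approx(g.area_cm2, rel=0.03)

    def test_tiny_instance_skipped_with_reason(self, default_plant):
        spec, labeled, truth = default_plant
        inst = labeled.instance.copy()
        # shrink leaf 0 to 10 points
        leaf0 = np.flatnonzero((labeled.semantic == 2) & (inst == 0))
        inst[leaf0[10:]] = -1
        from sesame3d import LabeledCloud

        small = LabeledCloud(labeled.cloud, labeled.semantic, inst)
        rep = extract_all_traits(small, None, truth.r)
        assert 0 not in [leaf.instance_id for leaf in rep.leaves]
        assert any(i == 0 for i, _ in rep.skipped)

    def test_no_stem_raises(self, default_plant):
        spec, labeled, truth = default_plant
        from sesame3d import LabeledCloud

        leaves_only = labeled.select(labeled.semantic == 2)
        with pytest.raises(ValueError, match="stem"):
            extract_all_traits(leaves_only, None, truth.r)
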