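import itertools

import numpy as np
import pytest

from sesame3d import (
    CAVFPointNetSegmenter,
    NetworkConfig,
    TrainConfig,
    ball_query,
    farthest_point_sampling,
    varifocal_loss,
)
from sesame3d.autodiff import Tensor
from sesame3d.network import (
    TOY_FP_MLPS,
    TOY_SA_CONFIG,
    CAABlock,
    interpolate_features,
    split_dataset,
)


def toy_model(**kw):
    defaults = dict(
        n_points=256,
        sa_config=TOY_SA_CONFIG,
        fp_mlps=TOY_FP_MLPS,
        epochs=5,
        batch_size=1,
        lr=0.005,
        validation_fraction=0.0,
        random_state=0,
    )
    defaults.update(kw)
    return CAVFPointNetSegmenter(**defaults)


class TestFarthestPointSampling:
    def test_collinear_picks_extreme(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [10, 0, 0]])
        idx = farthest_point_sampling(coords, 2, start_index=0)
        assert set(idx) == {0, 2}

    def test_m_equals_n_gives_all_indices(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(7, 3))
        idx = farthest_point_sampling(coords, 7, seed=1)
        assert sorted(idx) == list(range(7))

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_min_distance_property(self, seed):
        # each pick maximises the min distance to the chosen set (exhaustive)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        coords = rng.normal(size=(n, 3))
        m = int(rng.integers(2, n + 1))
        idx = farthest_point_sampling(coords, m, start_index=0)
        assert len(set(idx)) == m
        for step in range(1, m):
            chosen = coords[idx[:step]]
            min_d = np.linalg.norm(coords[:, None] - chosen[None], axis=2).min(axis=1)
            assert min_d[idx[step]] == pytest.approx(min_d.max())

    def test_seeded_start_and_errors(self):
        coords = np.random.default_rng(2).normal(size=(10, 3))
        a = farthest_point_sampling(coords, 4, seed=3)
        b = farthest_point_sampling(coords, 4, seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            farthest_point_sampling(coords, 11)


class TestBallQuery:
    def test_fill_rule_repeats_first_neighbor(self):
        coords = np.array([[0.5, 0, 0], [2.0, 0, 0]])
        idx = ball_query(coords, np.zeros((1, 3)), radius=1.0, s=2)
        np.testing.assert_array_equal(idx, [[0, 0]])

    def test_radius_covering_everything(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3))
        idx = ball_query(coords, coords[:1], radius=100.0, s=20)
        assert sorted(idx[0]) == list(range(20))

    def test_empty_neighborhood_falls_back_to_nearest(self):
        coords = np.array([[5.0, 0, 0], [9.0, 0, 0]])
        idx = ball_query(coords, np.zeros((1, 3)), radius=0.1, s=3)
        np.testing.assert_array_equal(idx, [[0, 0, 0]])

    @pytest.mark.parametrize("seed", range(3))
    def test_membership_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        coords = rng.uniform(0, 1, (n, 3))
        centers = rng.uniform(0, 1, (10, 3))
        radius = float(rng.uniform(0.1, 0.4))
        s = 16
        idx = ball_query(coords, centers, radius, s)
        d = np.linalg.norm(coords[None] - centers[:, None], axis=2)
        for ci in range(10):
            within = np.flatnonzero(d[ci] <= radius)
            if within.size:
                assert set(idx[ci]) <= set(within)
                # the first min(s, |within|) indices in ascending order
                np.testing.assert_array_equal(
                    idx[ci, : min(s, within.size)], within[:s]
                )


class TestCAABlock:
    def test_output_in_open_unit_interval_and_shape(self):
        rng = np.random.default_rng(0)
        blk = CAABlock(8, reduction=2, kernel=3, rng=rng)
        x = rng.normal(size=(6, 5, 8))
        att = blk(Tensor(x)).data
        assert att.shape == x.shape
        assert (att > 0).all() and (att < 1).all()

    def test_matches_hand_rolled_five_stage_reference(self):
        rng = np.random.default_rng(1)
        c = 2
        blk = CAABlock(c, reduction=1, kernel=3, rng=np.random.default_rng(2))
        x = rng.normal(size=(4, 4, c))
        att = blk(Tensor(x)).data

        def ref_dwconv(a, kern, axis):
            k = kern.shape[0]
            pad = (k - 1) // 2
            length = a.shape[axis]
            pads = [(0, 0)] * a.ndim
            pads[axis] = (pad, k - 1 - pad)
            ap = np.pad(a, pads)
            out = np.zeros_like(a)
            for j in range(k):
                sl = [slice(None)] * a.ndim
                sl[axis] = slice(j, j + length)
                out += ap[tuple(sl)] * kern[j]
            return out

        # stage 1: global average pool
        a = x.mean(axis=(0, 1), keepdims=True)
        # stage 2: 1x1 conv channel reduction
        a = a @ blk.w1.data + blk.b1.data
        # stage 3 + 4: horizontal then vertical depthwise conv
        a = ref_dwconv(a, blk.kh.data, axis=1)
        a = ref_dwconv(a, blk.kv.data, axis=0)
        # stage 5: 1x1 fusion conv + sigmoid, broadcast to input shape
        a = a @ blk.w2.data + blk.b2.data
        ref = (1.0 / (1.0 + np.exp(-a))) * np.ones((4, 4, 1))
        np.testing.assert_allclose(att, ref, atol=1e-12)


class TestAblationIdentities:
    @staticmethod
    def _shared_params(model):
        out = []
        for lvl in model._sa_levels:
            for _, _, mlp, _ in lvl.scales:
                out += mlp.params()
        for fp in model._fp_levels:
            out += fp.params()
        out += model._head.params()
        return out

    def test_caa_disabled_equals_attention_forced_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 6))
        off = toy_model(caa_enabled=False)
        on = toy_model(caa_enabled=True)
        off._build(np.random.default_rng(5))
        on._build(np.random.default_rng(5))
        for a, b in zip(self._shared_params(off), self._shared_params(on)):
            b.data = a.data.copy()
        for lvl in on._sa_levels:
            for _, _, _, caa in lvl.scales:
                caa.w2.data[:] = 0.0
                caa.b2.data[:] = 1e9  # sigmoid saturates to 1
        la = off.forward_logits(X, np.random.default_rng(9)).data
        lb = on.forward_logits(X, np.random.default_rng(9)).data
        np.testing.assert_array_equal(la, lb)

    def test_vfl_printed_form_at_q1_equals_cross_entropy(self):
        p = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(varifocal_loss(p, 1.0, gamma=2.0), -np.log(p))

    def test_vfl_printed_form_gamma_inert_for_hard_labels(self):
        p = np.linspace(0.05, 0.95, 10)
        for q in (0.0, 1.0):
            a = varifocal_loss(p, q, gamma=0.5)
            b = varifocal_loss(p, q, gamma=5.0)
            np.testing.assert_allclose(a, b)


class TestVarifocalLoss:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            (0.5, 1.0, -np.log(0.5)),
            (0.2, 0.0, -np.log(0.8)),
            (0.7, 0.5, 0.5 * -np.log(0.7) + 0.25 * -np.log(0.3)),
        ],
    )
    def test_printed_form_hand_values(self, p, q, expected):
        assert varifocal_loss(p, q, gamma=2.0) == pytest.approx(expected)

    def test_original_form_keeps_gamma_active_for_negatives(self):
        a = varifocal_loss(0.3, 0.0, gamma=1.0, form="original-vfl")
        b = varifocal_loss(0.3, 0.0, gamma=3.0, form="original-vfl")
        assert a != pytest.approx(b)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            varifocal_loss(1.0, 0.5)
        with pytest.raises(ValueError):
            varifocal_loss(0.5, 1.5)


class TestFeaturePropagation:
    def test_exact_hit_takes_source_feature(self):
        src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5]])
        idx, w = interpolate_features(src, np.array([[1.0, 0, 0]]))
        feats = np.array([[10.0], [20.0], [30.0], [40.0]])
        interp = (feats[idx] * w[..., None]).sum(axis=1)
        assert interp[0, 0] == pytest.approx(20.0, abs=1e-6)

    def test_equidistant_pair_averages(self):
        src = np.array([[-1.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        idx, w = interpolate_features(src, np.array([[0.0, 0, 0]]))
        feats = np.array([[0.0], [2.0], [50.0]])
        interp = (feats[idx] * w[..., None]).sum(axis=1)
        # the far third source carries ~1e-4 of the weight
        assert interp[0, 0] == pytest.approx(1.0, abs=0.01)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        src, dst = rng.normal(size=(30, 3)), rng.normal(size=(50, 3))
        _, w = interpolate_features(src, dst)
        np.testing.assert_allclose(w.sum(axis=1), 1.0)

    def test_empty_source_raises(self):
        with pytest.raises(ValueError):
            interpolate_features(np.empty((0, 3)), np.zeros((2, 3)))


class TestModelContracts:
    @pytest.mark.parametrize("n", [1, 7, 200])
    def test_shape_conservation(self, n):
        rng = np.random.default_rng(5)
        model = toy_model()
        model._build(np.random.default_rng(0))
        X = rng.normal(size=(n, 6))
        logits = model.forward_logits(X, np.random.default_rng(1))
        assert logits.data.shape == (n, 3)

    def test_predict_labels_valid_and_deterministic(self, tiny_training_set):
        clouds, labels = tiny_training_set
        model = toy_model(epochs=2)
        model.fit(clouds[:2], labels[:2])
        out1 = model.predict_one(clouds[0])
        out2 = model.predict_one(clouds[0])
        assert out1.shape == (len(clouds[0]),)
        assert set(np.unique(out1)) <= {0, 1, 2}
        np.testing.assert_array_equal(out1, out2)

    def test_fixed_seed_reproduces_epoch0_loss(self, tiny_training_set):
        clouds, labels = tiny_training_set
        losses = []
        for _ in range(2):
            m = toy_model(epochs=1)
            m.fit(clouds, labels)
            losses.append(m.history_[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_split_8_1_1_counts(self):
        train, val, test = split_dataset(10, (0.8, 0.1, 0.1), seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)
        assert sorted(np.concatenate([train, val, test])) == list(range(10))

    def test_train_loss_decreases_on_tiny_set(self, tiny_training_set):
        clouds, labels = tiny_training_set
        model = toy_model(epochs=10)
        model.fit(clouds, labels)
        hist = model.history_
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            toy_model().fit([], [])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            NetworkConfig(
                sa_config=[{"n_centers": 4, "scales": [
                    {"radius": 0.2, "n_samples": 4, "mlp": [8]},
                    {"radius": 0.1, "n_samples": 4, "mlp": [8]},
                ]}]
            )
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2))
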