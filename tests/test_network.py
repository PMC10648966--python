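"""Network: SPP geometry, forward/backward mechanics, toy convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrmixid import (
    ModelConfig,
    PairSet,
    TrainedModel,
    build_model,
    predict_pairs,
    spp_output_length,
    spp_pool,
    train,
)
from nmrmixid.network import _bce_with_logits

TOY_CFG = dict(
    n_conv_blocks=3,
    conv_kernels=8,
    conv2d_kernels=16,
    spp_levels=(4, 3, 2, 1),
    dense_units=16,
)


def brute_force_spp(fm, levels):
    """Enumerate every bin index set explicitly and take per-channel maxima."""
    H, W, C = fm.shape
    out = []
    for n in levels:
        hb = [(i * H) // n for i in range(n + 1)]
        wb = [(j * W) // n for j in range(n + 1)]
        for i in range(n):
            for j in range(n):
                vals = [
                    fm[h, w, :]
                    for h in range(hb[i], hb[i + 1])
                    for w in range(wb[j], wb[j + 1])
                ]
                out.append(np.max(vals, axis=0))
    return np.concatenate(out)


class TestSPP:
    def test_four_level_pyramid_gives_3840_features(self, rng):
        fm = rng.random((64, 7, 128))
        v = spp_pool(fm, (4, 3, 2, 1))
        assert v.shape == (3840,)
        assert spp_output_length(128, (4, 3, 2, 1)) == 3840

    def test_length_independent_of_map_shape(self, rng):
        for H, W in [(4, 4), (9, 5), (64, 7), (17, 23), (128, 4)]:
            assert spp_pool(rng.random((H, W, 16)), (4, 3, 2, 1)).size == 16 * 30

    def test_1x1_map_single_level_is_identity(self, rng):
        fm = rng.random((1, 1, 5))
        assert np.array_equal(spp_pool(fm, (1,)), fm[0, 0, :])

    def test_matches_brute_force_oracle_on_small_maps(self, rng):
        for H in range(1, 9):
            for W in range(1, 9):
                levels = tuple(n for n in (4, 3, 2, 1) if n <= min(H, W))
                fm = rng.random((H, W, 2))
                assert np.array_equal(spp_pool(fm, levels), brute_force_spp(fm, levels))

    def test_level_exceeding_map_is_error(self, rng):
        with pytest.raises(ValueError, match="level"):
            spp_pool(rng.random((3, 3, 2)), (4,))

    @given(
        H=st.integers(4, 40), W=st.integers(4, 40), C=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_output_length_property(self, H, W, C, seed):
        fm = np.random.default_rng(seed).random((H, W, C))
        assert spp_pool(fm, (4, 3, 2, 1)).size == C * 30


class TestBuildModel:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(n_conv_blocks=0)
        with pytest.raises(ValueError):
            ModelConfig(spp_levels=())
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)

    def test_same_seed_identical_init(self):
        a = build_model(ModelConfig(**TOY_CFG, seed=5))
        b = build_model(ModelConfig(**TOY_CFG, seed=5))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_branches_do_not_share_weights(self):
        net = build_model(ModelConfig(**TOY_CFG, seed=5))
        w0 = net.branches[0][0].W.value
        w1 = net.branches[1][0].W.value
        assert w0.shape == w1.shape and not np.array_equal(w0, w1)

    def test_spp_absorbs_different_input_lengths(self, rng):
        net = build_model(ModelConfig(**TOY_CFG, seed=0))
        for P in (2048, 4096):
            z = net.forward_logits(
                rng.random((2, P)).astype(np.float32),
                rng.random((2, P)).astype(np.float32),
            )
            assert z.shape == (2,)

    def test_probabilities_in_unit_interval(self, rng):
        net = build_model(ModelConfig(**TOY_CFG, seed=0))
        p = net.predict_proba(rng.random((4, 512)), rng.random((4, 512)))
        assert np.all((p >= 0) & (p <= 1))

    def test_too_short_input_is_error(self, rng):
        net = build_model(ModelConfig(seed=0))  # 9 blocks -> needs >= 4*512
        with pytest.raises(ValueError, match="too short"):
            net.forward_logits(rng.random((1, 512)), rng.random((1, 512)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = ModelConfig(n_conv_blocks=2, conv_kernels=3, conv2d_kernels=4,
                          spp_levels=(2, 1), dense_units=5, dropout_rate=0.0, seed=3)
        net = build_model(cfg)
        for p in net.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        refs, comps = rng.random((3, 32)), rng.random((3, 32))
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            return _bce_with_logits(net.forward_logits(refs, comps, training=True), y)

        _, dz = loss()
        net.zero_grad()
        net.backward(dz)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for p in net.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for _ in range(3):
                i = check_rng.integers(flat.size)
                old = flat[i]
                flat[i] = old + eps
                lp, _ = loss()
                flat[i] = old - eps
                lm, _ = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grad[i], rel=1e-3, abs=1e-7)


class TestTraining:
    @staticmethod
    def _toy_pairs(n=40, P=256, seed=0):
        """Linearly separable toy task: positives are identical spectra,
        negatives live on disjoint support."""
        rng = np.random.default_rng(seed)
        refs = np.zeros((n, P), dtype=np.float32)
        comps = np.zeros((n, P), dtype=np.float32)
        labels = np.zeros(n, dtype=np.int8)
        for i in range(n):
            a = rng.random(P).astype(np.float32)
            if i % 2 == 0:  # positive: same signal
                refs[i] = a
                comps[i] = a
                labels[i] = 1
            else:  # negative: orthogonal supports
                refs[i, : P // 2] = a[: P // 2]
                comps[i, P // 2 :] = a[P // 2 :]
        return PairSet(refs, comps, labels)

    def test_initial_loss_near_ln2_for_balanced_labels(self):
        pairs = self._toy_pairs()
        net = build_model(ModelConfig(**TOY_CFG, seed=1))
        z = net.forward_logits(pairs.references, pairs.composites)
        loss, _ = _bce_with_logits(z, pairs.labels.astype(float))
        assert loss == pytest.approx(np.log(2), abs=0.25)

    def test_converges_on_separable_toy_task(self):
        pairs = self._toy_pairs()
        cfg = ModelConfig(**TOY_CFG, epochs=20, learning_rate=1e-3,
                          batch_size=8, seed=1)
        fitted = train(build_model(cfg), pairs, None, cfg)
        p = predict_pairs(fitted, pairs)
        acc = np.mean((p > 0.5) == (pairs.labels > 0.5))
        assert acc == pytest.approx(1.0)
        assert len(fitted.history["loss"]) == 20

    def test_reproducible_training(self):
        pairs = self._toy_pairs(n=16)
        cfg = ModelConfig(**TOY_CFG, epochs=2, learning_rate=1e-3, batch_size=8, seed=4)
        a = train(build_model(cfg), pairs, None, cfg)
        b = train(build_model(cfg), pairs, None, cfg)
        for pa, pb in zip(a.network.params(), b.network.params()):
            assert np.array_equal(pa.value, pb.value)
        assert a.history == b.history

    def test_single_class_warns(self):
        pairs = self._toy_pairs(n=8)
        pairs.labels[:] = 1
        cfg = ModelConfig(**TOY_CFG, epochs=1, batch_size=8, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            train(build_model(cfg), pairs, None, cfg)

    def test_empty_training_set_is_error(self):
        cfg = ModelConfig(**TOY_CFG, epochs=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(build_model(cfg), PairSet.from_pairs([]), None, cfg)


class TestPredictPairs:
    def test_empty_input_empty_output(self):
        net = build_model(ModelConfig(**TOY_CFG, seed=0))
        assert predict_pairs(net, PairSet.from_pairs([])).size == 0

    def test_batching_equivalence(self, rng):
        pairs = TestTraining._toy_pairs(n=10)
        net = build_model(ModelConfig(**TOY_CFG, seed=2))
        full = predict_pairs(net, pairs, batch_size=10)
        singles = np.concatenate(
            [predict_pairs(net, pairs.subset(np.array([i])), batch_size=1)
             for i in range(10)]
        )
        assert np.allclose(full, singles, atol=1e-6)

    def test_batch_permutation_equivariance(self, rng):
        pairs = TestTraining._toy_pairs(n=12)
        net = build_model(ModelConfig(**TOY_CFG, seed=2))
        perm = rng.permutation(12)
        p_full = predict_pairs(net, pairs, batch_size=12)
        p_perm = predict_pairs(net, pairs.subset(perm), batch_size=12)
        assert np.allclose(p_full[perm], p_perm, atol=1e-6)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        pairs = TestTraining._toy_pairs(n=8)
        cfg = ModelConfig(**TOY_CFG, epochs=1, batch_size=8, seed=6)
        fitted = train(build_model(cfg), pairs, None, cfg)
        path = tmp_path / "model.npz"
        fitted.save(path)
        back = TrainedModel.load(path)
        assert back.config == fitted.config
        assert back.history == fitted.history
        assert np.allclose(
            back.predict_proba(pairs.references, pairs.composites),
            fitted.predict_proba(pairs.references, pairs.composites),
            atol=1e-7,
        )
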