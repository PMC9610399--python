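"""SE primitives, network construction, training behavior, persistence."""

import numpy as np
import pytest

from pandacall._layers import SEBlock
from pandacall.loss import make_cross_entropy
from pandacall.model import ModelConfig, build_model, se_excite, se_rescale, se_squeeze, train
from pandacall.model import test_profile as light_profile

TINY = ModelConfig(
    input_shape=(1, 20, 16),
    stem_channels=4,
    stem_kernel=3,
    stem_stride=2,
    stage_channels=(8,),
    epochs=5,
    seed=3,
)


def toy_batch(n=8, seed=0, shape=(1, 20, 16)):
    gen = np.random.default_rng(seed)
    return gen.normal(0, 1, (n, *shape)).astype(np.float32)


class TestSEPrimitives:
    def test_squeeze_of_constant_channel(self):
        fmap = np.full((3, 4, 5), 3.0)
        assert np.allclose(se_squeeze(fmap), 3.0)

    def test_squeeze_direct_mean(self):
        fmap = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert se_squeeze(fmap)[0] == pytest.approx(2.5)

    def test_squeeze_matches_double_loop(self):
        fmap = np.random.default_rng(0).normal(0, 1, (6, 7, 9))
        brute = np.empty(6)
        for c in range(6):
            acc = 0.0
            for i in range(7):
                for j in range(9):
                    acc += fmap[c, i, j]
            brute[c] = acc / 63
        assert np.allclose(se_squeeze(fmap), brute, atol=1e-9)

    def test_squeeze_linearity(self):
        fmap = np.random.default_rng(1).normal(0, 1, (4, 5, 5))
        assert np.allclose(se_squeeze(3.5 * fmap), 3.5 * se_squeeze(fmap))

    def test_excite_zero_params_give_half(self):
        z = np.random.default_rng(2).normal(0, 1, 8)
        w = se_excite(z, np.zeros((2, 8)), np.zeros(2), np.zeros((8, 2)), np.zeros(8))
        assert np.allclose(w, 0.5)

    def test_excite_bounded_open_interval(self):
        gen = np.random.default_rng(3)
        for _ in range(1000):
            c, r = 8, 4
            w = se_excite(
                gen.normal(0, 1, c),
                gen.normal(0, 1, (c // r, c)),
                gen.normal(0, 1, c // r),
                gen.normal(0, 1, (c, c // r)),
                gen.normal(0, 1, c),
            )
            assert np.all(w > 0.0) and np.all(w < 1.0)

    def test_excite_monotone_through_positive_path(self):
        # 1-channel toy with positive weights: more activation, more gate
        w1, b1 = np.array([[2.0]]), np.array([0.0])
        w2, b2 = np.array([[1.5]]), np.array([0.0])
        lo = se_excite(np.array([0.1]), w1, b1, w2, b2)
        hi = se_excite(np.array([0.2]), w1, b1, w2, b2)
        assert hi[0] > lo[0]

    def test_rescale_exact(self):
        fmap = np.ones((2, 3, 3))
        out = se_rescale(fmap, np.array([0.5, 2.0]))
        assert np.all(out[0] == 0.5)
        assert np.all(out[1] == 2.0)

    def test_rescale_identity_and_zero(self):
        fmap = np.random.default_rng(4).normal(0, 1, (3, 4, 4))
        assert np.array_equal(se_rescale(fmap, np.ones(3)), fmap)
        assert np.all(se_rescale(fmap, np.zeros(3)) == 0.0)

    def test_rescale_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            se_rescale(np.ones((3, 2, 2)), np.ones(2))


class TestSEBlockLayer:
    def test_forced_unit_excitation_is_identity(self):
        rng = np.random.default_rng(0)
        block = SEBlock(8, 4, rng)
        # saturate the sigmoid so the gate is 1 to float precision
        block.w1.value[...] = 0.0
        block.w2.value[...] = 0.0
        block.b1.value[...] = 0.0
        block.b2.value[...] = 60.0
        x = np.random.default_rng(1).normal(0, 1, (2, 8, 5, 5)).astype(np.float32)
        assert np.array_equal(block.forward(x, train=False), x)

    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(5)
        block = SEBlock(4, 2, rng)
        x = np.random.default_rng(6).normal(0, 1, (2, 4, 3, 3)).astype(np.float64)

        def scalar_out(xv):
            return float(block.forward(xv.astype(np.float32), train=False).sum())

        y = block.forward(x.astype(np.float32), train=True)
        dx = block.backward(np.ones_like(y))
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (1, 2, 1, 2), (0, 3, 2, 1)]:
            up = x.copy()
            up[idx] += eps
            down = x.copy()
            down[idx] -= eps
            numeric = (scalar_out(up) - scalar_out(down)) / (2 * eps)
            assert dx[idx] == pytest.approx(numeric, rel=1e-2, abs=1e-3)


class TestBuildModel:
    def test_forward_outputs_probability_pair(self):
        model = build_model(light_profile(seed=1))
        x = toy_batch(4, shape=(1, 173, 64))
        probs = model.predict_proba(x)
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_parameters(self):
        a = build_model(light_profile(seed=7))
        b = build_model(light_profile(seed=7))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_se_ablation_changes_param_count_by_affine_sizes(self):
        cfg = light_profile(seed=0)
        with_se = build_model(cfg)
        without = build_model(ModelConfig(**{**cfg.__dict__, "use_se": False}))
        expected = 0
        for c in cfg.stage_channels:
            hidden = max(1, c // cfg.reduction_ratio)
            expected += hidden * c + hidden + c * hidden + c
        assert with_se.parameter_count() - without.parameter_count() == expected

    def test_batching_invariance(self):
        model = build_model(light_profile(seed=2))
        x = toy_batch(5, shape=(1, 173, 64))
        full = model.predict_proba(x)
        single = model.predict_proba(x[2:3])
        assert np.allclose(full[2], single[0], atol=1e-6)

    def test_untrained_symmetricish_outputs(self):
        # averaged over random inits and inputs, the output is near uniform
        means = []
        for s in range(20):
            model = build_model(light_profile(seed=s))
            probs = model.predict_proba(toy_batch(50, seed=100 + s, shape=(1, 173, 64)))
            means.append(probs[:, 0].mean())
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_shape_mismatch_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="expected"):
            model.predict_proba(toy_batch(2, shape=(1, 173, 64)))


class TestTraining:
    def separable_data(self, n=50):
        gen = np.random.default_rng(0)
        x = gen.normal(0, 0.3, (n, 1, 20, 16)).astype(np.float32)
        y = gen.integers(0, 2, n)
        x[y == 1, :, :10, :] += 3.0  # strong localized offset
        return x, y

    def test_separable_toy_reaches_full_accuracy(self):
        x, y = self.separable_data()
        cfg = ModelConfig(**{**TINY.__dict__, "epochs": 40})
        model = build_model(cfg)
        log = train(model, x, y, config=cfg)
        assert (model.predict(x) == y).mean() == 1.0
        assert log.epoch_loss[-1] < log.epoch_loss[0]

    def test_zero_epochs_leaves_model_unchanged(self):
        x, y = self.separable_data(10)
        cfg = ModelConfig(**{**TINY.__dict__, "epochs": 0})
        model = build_model(cfg)
        before = [p.value.copy() for p in model.params()]
        train(model, x, y, config=cfg)
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)

    def test_same_seed_identical_training_curve(self):
        x, y = self.separable_data(30)
        logs = []
        for _ in range(2):
            model = build_model(TINY)
            logs.append(train(model, x, y, config=TINY).epoch_loss)
        assert logs[0] == logs[1]

    def test_empty_training_set_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="empty"):
            train(model, np.empty((0, 1, 20, 16), dtype=np.float32), np.array([]))

    def test_end_to_end_gradient_check_through_network(self):
        """Numerical vs analytic gradient of the full loss wrt head weights."""
        x, y = self.separable_data(6)
        model = build_model(TINY)
        model.fit_normalizer(x)
        loss_fn = make_cross_entropy()
        head = model.layers[-1].w

        def loss_at(wval):
            head.value[...] = wval
            return loss_fn(model.forward(x, train=False), y)[0]

        base = head.value.copy()
        logits = model.forward(x, train=True)
        _, dlogits = loss_fn(logits, y)
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(dlogits)
        analytic = head.grad.copy()
        eps = 1e-3
        for idx in [(0, 0), (1, 3), (0, 5)]:
            up = base.copy()
            up[idx] += eps
            down = base.copy()
            down[idx] -= eps
            numeric = (loss_at(up) - loss_at(down)) / (2 * eps)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-2, abs=1e-4)
        head.value[...] = base


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        x, y = TestTraining().separable_data(12)
        model = build_model(TINY)
        train(model, x, y, config=TINY)
        path = tmp_path / "model.npz"
        model.save(path)
        back = type(model).load(path)
        assert back.config == model.config
        assert np.allclose(back.predict_proba(x), model.predict_proba(x), atol=1e-7)
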