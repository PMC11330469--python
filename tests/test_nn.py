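import numpy as np
import pytest
from scipy import ndimage

from radiofusion import nn


def finite_difference_gradcheck(layer, x, loss_weights, eps=1e-5):
    """Compare analytic parameter/input gradients with central differences.

    Everything is promoted to float64; the scalar loss is sum(out * W) for a
    fixed random W so the output gradient is simply W.
    """
    for p in layer.params:
        layer.params[p] = layer.params[p].astype(np.float64)
    x = x.astype(np.float64)

    def loss():
        return float((layer.forward(x, training=True) * loss_weights).sum())

    loss()
    dx = layer.backward(loss_weights.astype(np.float64))
    checks = {}
    if dx is not None:
        num = np.zeros_like(x)
        it = np.ndindex(*x.shape)
        for idx in it:
            orig = x[idx]
            x[idx] = orig + eps
            lp = loss()
            x[idx] = orig - eps
            lm = loss()
            x[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        checks["x"] = (dx, num)
    for name, p in layer.params.items():
        loss()
        layer.backward(loss_weights.astype(np.float64))
        analytic = layer.grads[name].copy()
        num = np.zeros_like(p, dtype=np.float64)
        for idx in np.ndindex(*p.shape):
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        checks[name] = (analytic, num)
    for name, (analytic, num) in checks.items():
        err = np.abs(analytic - num)
        scale = np.maximum(np.abs(num), 1e-3)
        assert np.max(err / scale) < 1e-4, f"{name}: max rel err {np.max(err / scale)}"


class TestConv3d:
    def test_matches_scipy_correlate(self, rng):
        conv = nn.Conv3d(2, 3, 3, rng, gain=1.0)
        x = rng.normal(size=(2, 2, 5, 5, 5)).astype(np.float32)
        out = conv.forward(x, training=False)
        w = conv.params["w"].reshape(3, 2, 3, 3, 3)
        for b in range(2):
            for o in range(3):
                ref = sum(
                    ndimage.correlate(
                        x[b, c].astype(np.float64),
                        w[o, c].astype(np.float64),
                        mode="constant",
                    )
                    for c in range(2)
                ) + conv.params["b"][o]
                assert np.allclose(out[b, o], ref, atol=1e-4)

    def test_gradcheck(self, rng):
        conv = nn.Conv3d(2, 2, 3, rng, gain=1.0)
        x = rng.normal(size=(2, 2, 4, 4, 4))
        lw = rng.normal(size=(2, 2, 4, 4, 4))
        finite_difference_gradcheck(conv, x, lw)

    def test_no_input_grad_mode_returns_none(self, rng):
        conv = nn.Conv3d(1, 2, 3, rng, gain=1.0, needs_input_grad=False)
        x = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        conv.forward(x, training=True)
        assert conv.backward(np.ones((1, 2, 4, 4, 4), np.float32)) is None
        assert conv.grads["w"].shape == conv.params["w"].shape

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            nn.Conv3d(1, 1, 2, rng, gain=1.0)


class TestBatchNorm:
    def test_normalizes_batch_statistics(self, rng):
        bn = nn.BatchNorm(4)
        x = rng.normal(3.0, 5.0, size=(8, 4, 3, 3, 3)).astype(np.float32)
        out = bn.forward(x, training=True)
        assert np.allclose(out.mean(axis=(0, 2, 3, 4)), 0.0, atol=1e-4)
        assert np.allclose(out.std(axis=(0, 2, 3, 4)), 1.0, atol=1e-2)

    def test_eval_uses_running_statistics(self, rng):
        bn = nn.BatchNorm(2)
        x = rng.normal(2.0, 3.0, size=(16, 2)).astype(np.float32)
        for _ in range(200):
            bn.forward(x, training=True)
        out = bn.forward(x, training=False)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-2)

    def test_gradcheck(self, rng):
        bn = nn.BatchNorm(3)
        x = rng.normal(size=(4, 3, 2, 2, 2))
        lw = rng.normal(size=(4, 3, 2, 2, 2))
        finite_difference_gradcheck(bn, x, lw)

    def test_gradcheck_2d(self, rng):
        bn = nn.BatchNorm(5)
        x = rng.normal(size=(7, 5))
        lw = rng.normal(size=(7, 5))
        finite_difference_gradcheck(bn, x, lw)


class TestLeakyReLU:
    def test_forward_values(self):
        act = nn.LeakyReLU(0.01)
        x = np.array([-2.0, -0.5, 0.0, 1.5], np.float32)
        out = act.forward(x, training=True)
        assert np.allclose(out, [-0.02, -0.005, 0.0, 1.5])

    def test_gradcheck(self, rng):
        act = nn.LeakyReLU(0.01)
        x = rng.normal(size=(5, 4)) + 0.1  # keep away from the kink
        lw = rng.normal(size=(5, 4))
        finite_difference_gradcheck(act, x, lw)


class TestMaxPool3d:
    def test_matches_blockwise_max(self, rng):
        pool = nn.MaxPool3d()
        x = rng.normal(size=(2, 3, 6, 6, 6)).astype(np.float32)
        for training in (True, False):
            out = pool.forward(x, training)
            ref = x.reshape(2, 3, 3, 2, 3, 2, 3, 2).max(axis=(3, 5, 7))
            assert np.array_equal(out, ref)

    def test_odd_trailing_voxels_cropped(self, rng):
        pool = nn.MaxPool3d()
        x = rng.normal(size=(1, 1, 5, 5, 5)).astype(np.float32)
        out = pool.forward(x, training=False)
        assert out.shape == (1, 1, 2, 2, 2)
        ref = x[:, :, :4, :4, :4].reshape(1, 1, 2, 2, 2, 2, 2, 2).max(axis=(3, 5, 7))
        assert np.array_equal(out, ref)

    def test_backward_routes_gradient_to_argmax(self):
        pool = nn.MaxPool3d()
        x = np.zeros((1, 1, 2, 2, 2), np.float32)
        x[0, 0, 1, 0, 1] = 5.0
        pool.forward(x, training=True)
        dx = pool.backward(np.full((1, 1, 1, 1, 1), 2.0, np.float32))
        expected = np.zeros_like(x)
        expected[0, 0, 1, 0, 1] = 2.0
        assert np.array_equal(dx, expected)

    def test_gradcheck(self, rng):
        pool = nn.MaxPool3d()
        x = rng.normal(size=(2, 2, 4, 4, 4))
        lw = rng.normal(size=(2, 2, 2, 2, 2))
        finite_difference_gradcheck(pool, x, lw)


class TestDropout:
    def test_identity_at_eval_and_p_zero(self, rng):
        x = rng.normal(size=(4, 4)).astype(np.float32)
        d = nn.Dropout(0.5)
        d.rng = rng
        assert np.array_equal(d.forward(x, training=False), x)
        d0 = nn.Dropout(0.0)
        assert np.array_equal(d0.forward(x, training=True), x)

    def test_inverted_scaling_preserves_expectation(self):
        d = nn.Dropout(0.3)
        d.rng = np.random.default_rng(0)
        x = np.ones((200, 200), np.float32)
        out = d.forward(x, training=True)
        kept = out[out > 0]
        assert np.allclose(kept, 1.0 / 0.7, atol=1e-5)
        assert abs(out.mean() - 1.0) < 0.02

    def test_requires_rng_in_training(self):
        d = nn.Dropout(0.5)
        with pytest.raises(RuntimeError, match="rng"):
            d.forward(np.ones((2, 2), np.float32), training=True)

    def test_backward_uses_same_mask(self):
        d = nn.Dropout(0.5)
        d.rng = np.random.default_rng(1)
        x = np.ones((10, 10), np.float32)
        out = d.forward(x, training=True)
        grad = d.backward(np.ones_like(x))
        assert np.array_equal(grad, out)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            nn.Dropout(1.0)


class TestGlobalAvgPoolAndLinear:
    def test_gap_matches_mean(self, rng):
        gap = nn.GlobalAvgPool()
        x = rng.normal(size=(3, 5, 4, 4, 4)).astype(np.float32)
        assert np.allclose(gap.forward(x, True), x.mean(axis=(2, 3, 4)))

    def test_gap_gradcheck(self, rng):
        gap = nn.GlobalAvgPool()
        finite_difference_gradcheck(
            gap, rng.normal(size=(2, 3, 2, 2, 2)), rng.normal(size=(2, 3))
        )

    def test_linear_gradcheck(self, rng):
        lin = nn.Linear(4, 3, rng, gain=1.0)
        finite_difference_gradcheck(
            lin, rng.normal(size=(5, 4)), rng.normal(size=(5, 3))
        )


class TestLosses:
    def test_cross_entropy_matches_scipy(self, rng):
        from scipy.special import log_softmax

        logits = rng.normal(size=(6, 3))
        y = rng.integers(0, 3, 6)
        loss, dlogits = nn.cross_entropy(logits, y)
        ref = -log_softmax(logits, axis=1)[np.arange(6), y].mean()
        assert loss == pytest.approx(float(ref), rel=1e-6)
        # gradient rows sum to zero and average to the softmax residual
        assert np.allclose(dlogits.sum(axis=1), 0.0, atol=1e-6)

    def test_cross_entropy_gradient_finite_difference(self, rng):
        logits = rng.normal(size=(4, 3))
        y = np.array([0, 1, 2, 1])
        _, d = nn.cross_entropy(logits, y)
        eps = 1e-5
        for idx in np.ndindex(4, 3):
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (nn.cross_entropy(lp, y)[0] - nn.cross_entropy(lm, y)[0]) / (2 * eps)
            assert d[idx] == pytest.approx(num, abs=1e-5)

    def test_mse_hand_value_and_gradient(self):
        pred = np.array([[1.0, 2.0]])
        target = np.array([[0.0, 0.0]])
        loss, d = nn.mse(pred, target)
        assert loss == pytest.approx(2.5)
        assert np.allclose(d, [[1.0, 2.0]])

    def test_softmax_rows_sum_to_one_and_shift_invariant(self, rng):
        z = rng.normal(size=(5, 3)) * 50
        p = nn.softmax(z)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(nn.softmax(z + 1000.0), p)


class TestOptimizerAndSchedule:
    def test_sgd_momentum_hand_computed(self, rng):
        lin = nn.Linear(1, 1, rng, gain=1.0)
        model = nn.Sequential([lin])
        opt = nn.SGD(model, momentum=0.9)
        w0 = float(lin.params["w"][0, 0])
        lin.grads["w"] = np.array([[2.0]], np.float32)
        lin.grads["b"] = np.array([0.0], np.float32)
        opt.step(lr=0.1)
        assert float(lin.params["w"][0, 0]) == pytest.approx(w0 - 0.2, abs=1e-6)
        opt.step(lr=0.1)  # velocity: 0.9*(-0.2) - 0.2 = -0.38
        assert float(lin.params["w"][0, 0]) == pytest.approx(w0 - 0.58, abs=1e-6)

    def test_cosine_schedule_endpoints_and_restart(self):
        assert nn.cosine_lr(0, 0.1, 50) == pytest.approx(0.1)
        assert nn.cosine_lr(25, 0.1, 50) == pytest.approx(0.05)
        assert nn.cosine_lr(50, 0.1, 50) == pytest.approx(0.1)  # warm restart
        assert nn.cosine_lr(49, 0.1, 50) < 0.001
        assert nn.cosine_lr(10, 0.1, 50, eta_min=0.01) > 0.01

    def test_kaiming_gain(self):
        assert nn.leaky_gain(0.0) == pytest.approx(np.sqrt(2.0))
        assert nn.leaky_gain(1.0) == pytest.approx(1.0)


class TestSequential:
    def test_state_dict_roundtrip(self, rng):
        model = nn.Sequential(
            [nn.Linear(4, 3, rng, 1.0), nn.BatchNorm(3), nn.LeakyReLU(0.01)]
        )
        x = rng.normal(size=(6, 4)).astype(np.float32)
        model.forward(x, training=True)  # move running stats off init
        state = model.state_dict()
        before = model.forward(x, training=False)
        model.layers[0].params["w"] += 1.0
        model.load_state_dict(state)
        after = model.forward(x, training=False)
        assert np.array_equal(before, after)

    def test_end_to_end_gradient_through_stack(self, rng):
        # a small composite network against finite differences
        layers = [
            nn.Conv3d(1, 2, 3, rng, 1.0),
            nn.LeakyReLU(0.01),
            nn.GlobalAvgPool(),
            nn.Linear(2, 2, rng, 1.0),
        ]
        model = nn.Sequential(layers)
        for layer in layers:
            for p in layer.params:
                layer.params[p] = layer.params[p].astype(np.float64)
        x = rng.normal(size=(2, 1, 4, 4, 4))
        y = np.array([0, 1])

        def loss():
            return nn.cross_entropy(model.forward(x, training=True), y)[0]

        out = model.forward(x, training=True)
        _, dout = nn.cross_entropy(out, y)
        model.backward(dout.astype(np.float64))
        w = layers[0].params["w"]
        g = layers[0].grads["w"]
        eps = 1e-6
        rng2 = np.random.default_rng(0)
        for _ in range(10):
            idx = tuple(rng2.integers(0, s) for s in w.shape)
            orig = w[idx]
            w[idx] = orig + eps
            lp = loss()
            w[idx] = orig - eps
            lm = loss()
            w[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-5)
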