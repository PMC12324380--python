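"""The numpy CNN engine: shapes, gradients, pooling, determinism."""

import numpy as np
import pytest

from sift2d.errors import ValidationError
from sift2d.network import (
    Adam,
    AdaptiveAvgPool2d,
    NetConfig,
    ResidualScorerNet,
)

TINY = NetConfig(stem_channels=2, stage_channels=(3,), blocks_per_stage=1, head_hidden=4)


class TestShapes:
    @pytest.mark.parametrize("side", [31, 64, 100, 150, 210])
    def test_pooled_trunk_is_6x6_and_scalar_output(self, side, rng):
        net = ResidualScorerNet(TINY, seed=0)
        img = rng.standard_normal((2, side, side))
        pooled = net.trunk(img, train=False)
        assert pooled.shape == (2, 3, 6, 6)
        scores = net.forward(img, np.zeros((2, 6)), train=False)
        assert scores.shape == (2,)
        assert np.all(np.isfinite(scores))

    def test_below_minimum_side_rejected(self):
        net = ResidualScorerNet(TINY, seed=0)
        with pytest.raises(ValidationError, match="31"):
            net.forward(np.zeros((1, 30, 30)), np.zeros((1, 6)))

    def test_shared_weights_accept_different_sizes(self, rng):
        net = ResidualScorerNet(TINY, seed=0)
        for side in (64, 210):
            s = net.forward(rng.standard_normal((1, side, side)), np.zeros((1, 6)), train=False)
            assert np.isfinite(s[0])

    def test_zero_head_gives_exactly_zero_score(self, rng):
        net = ResidualScorerNet(TINY, seed=0)
        for layer in net.head:
            for p in layer.parameters():
                p.value[...] = 0.0
        scores = net.forward(rng.standard_normal((3, 32, 32)), rng.standard_normal((3, 6)), train=False)
        assert np.all(scores == 0.0)


class TestGradients:
    def test_numerical_gradient_check(self, rng):
        """Analytic backprop matches central finite differences."""
        net = ResidualScorerNet(TINY, seed=0)
        x = rng.standard_normal((3, 32, 32))
        f = rng.standard_normal((3, 6))
        y = rng.standard_normal(3)

        def loss():
            return float(((net.forward(x, f, train=True) - y) ** 2).mean())

        pred = net.forward(x, f, train=True)
        net.zero_grad()
        net.backward(2 * (pred - y) / 3)
        for p in net.parameters():
            idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.value.shape)
            eps = 1e-6
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp = loss()
            p.value[idx] = orig - eps
            lm = loss()
            p.value[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            # conv biases feeding batch norm legitimately have ~zero gradient
            assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_gradient_flows_through_20_residual_blocks(self, rng):
        deep = NetConfig(stem_channels=2, stage_channels=(2, 2), blocks_per_stage=10, head_hidden=4)
        net = ResidualScorerNet(deep, seed=0)
        x = rng.standard_normal((4, 32, 32))
        pred = net.forward(x, np.zeros((4, 6)), train=True)
        net.zero_grad()
        net.backward(2 * (pred - np.ones(4)) / 4)
        first_conv_grad = np.linalg.norm(net.stem[0].w.grad)
        assert first_conv_grad > 1e-12


class TestAdaptivePool:
    @pytest.mark.parametrize("in_side", [4, 6, 7, 13, 50])
    def test_matches_brute_force_bounds(self, in_side, rng):
        pool = AdaptiveAvgPool2d(6)
        x = rng.standard_normal((1, 2, in_side, in_side))
        out = pool.forward(x)
        for i in range(6):
            r0, r1 = (i * in_side) // 6, -(-((i + 1) * in_side) // 6)
            expected = x[:, :, r0:r1, :].mean(axis=2, keepdims=True)
            for j in range(6):
                c0, c1 = (j * in_side) // 6, -(-((j + 1) * in_side) // 6)
                np.testing.assert_allclose(
                    out[:, :, i, j], x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
                )

    def test_backward_distributes_mass(self, rng):
        pool = AdaptiveAvgPool2d(6)
        x = rng.standard_normal((2, 3, 13, 13))
        pool.forward(x)
        dout = rng.standard_normal((2, 3, 6, 6))
        dx = pool.backward(dout)
        assert dx.shape == x.shape
        # the pooling is a mean: total gradient mass is conserved per cell
        assert dx.sum() == pytest.approx(dout.sum(), rel=1e-9)


class TestDeterminism:
    def test_inference_bitwise_reproducible(self, rng):
        net = ResidualScorerNet(TINY, seed=5)
        x = rng.standard_normal((2, 64, 64))
        f = rng.standard_normal((2, 6))
        a = net.forward(x, f, train=False)
        b = net.forward(x, f, train=False)
        assert np.array_equal(a, b)

    def test_same_seed_same_initial_weights(self):
        a = ResidualScorerNet(TINY, seed=9)
        b = ResidualScorerNet(TINY, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_adam_updates_parameters(self, rng):
        net = ResidualScorerNet(TINY, seed=0)
        opt = Adam(net.parameters(), lr=1e-2)
        x = rng.standard_normal((4, 32, 32))
        before = net.head[-1].w.value.copy()
        pred = net.forward(x, np.zeros((4, 6)), train=True)
        net.zero_grad()
        net.backward(2 * (pred - np.ones(4)) / 4)
        opt.step()
        assert not np.array_equal(before, net.head[-1].w.value)
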