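"""SE attention closed forms, Inception shape/parameter contracts, PPM."""

import numpy as np
import pytest

from pisunet.blocks import (
    InceptionBlock,
    PyramidPooling,
    SEBlock,
    se_excite,
    se_scale,
    se_squeeze,
)
from pisunet.model import count_parameters
from pisunet.nn import Linear, Tensor
from pisunet.nn import functional as F


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


class TestSESqueeze:
    def test_constant_map_squeezes_to_the_constant(self):
        a = np.full((2, 3, 4, 4), 2.5)
        np.testing.assert_allclose(se_squeeze(a).data, np.full((2, 3), 2.5))

    def test_hand_computed_average(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert se_squeeze(a).data[0, 0] == pytest.approx(2.5)

    def test_matches_double_sum_oracle_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.standard_normal((2, 4, 8, 8))
            z = se_squeeze(a).data
            # brute-force double loop over spatial positions
            h, w = a.shape[2:]
            oracle = np.zeros(a.shape[:2])
            for i in range(h):
                for j in range(w):
                    oracle += a[:, :, i, j]
            oracle /= h * w
            np.testing.assert_allclose(z, oracle, atol=1e-6)

    def test_invariant_under_spatial_permutation(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((1, 3, 6, 6))
        flat = a.reshape(1, 3, -1)
        perm = rng.permutation(36)
        shuffled = flat[:, :, perm].reshape(a.shape)
        np.testing.assert_allclose(se_squeeze(a).data, se_squeeze(shuffled).data, atol=1e-12)


class TestSEExcite:
    def _linear(self, weight, bias=None):
        w = np.atleast_2d(np.asarray(weight, dtype=np.float64))
        layer = Linear(w.shape[1], w.shape[0], np.random.default_rng(0))
        layer.weight = Tensor(w, requires_grad=True)
        layer.bias = Tensor(
            np.asarray(bias, dtype=np.float64) if bias is not None else np.zeros(w.shape[0]),
            requires_grad=True,
        )
        return layer

    def test_zero_weights_gate_to_one_half(self):
        w1 = self._linear(np.zeros((2, 4)))
        w2 = self._linear(np.zeros((4, 2)))
        s = se_excite(np.random.default_rng(0).standard_normal((3, 4)), w1, w2)
        np.testing.assert_allclose(s.data, 0.5)

    def test_hand_evaluated_two_layer_map(self):
        # C=2, bottleneck=1: W1=[1,1], W2=[[1],[-1]], z=[1,2] -> [sig(3), sig(-3)]
        w1 = self._linear([[1.0, 1.0]])
        w2 = self._linear([[1.0], [-1.0]])
        s = se_excite(np.array([[1.0, 2.0]]), w1, w2)
        np.testing.assert_allclose(s.data, [[_sigmoid(3.0), _sigmoid(-3.0)]], atol=1e-7)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(5)
        w1 = self._linear(rng.standard_normal((2, 8)))
        w2 = self._linear(rng.standard_normal((8, 2)))
        s = se_excite(rng.standard_normal((4, 8)) * 3, w1, w2).data
        assert np.all(s > 0) and np.all(s < 1)

    def test_dimension_mismatch_rejected(self):
        w1 = self._linear(np.zeros((2, 4)))
        w2 = self._linear(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            se_excite(np.zeros((1, 3)), w1, w2)


class TestSEScale:
    def test_ones_gate_is_identity(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((2, 3, 4, 4))
        np.testing.assert_array_equal(se_scale(a, np.ones((2, 3))).data, a)

    def test_zero_gate_nulls_the_map(self):
        a = np.ones((1, 2, 3, 3))
        assert np.all(se_scale(a, np.zeros((1, 2))).data == 0)

    def test_per_channel_rescaling(self):
        a = np.ones((1, 2, 2, 2))
        out = se_scale(a, np.array([[0.5, 2.0]])).data
        np.testing.assert_allclose(out[0, 0], 0.5)
        np.testing.assert_allclose(out[0, 1], 2.0)


class TestInception:
    def test_output_shape_and_spatial_preservation(self):
        rng = np.random.default_rng(0)
        block = InceptionBlock(8, 16, rng)
        out = block(np.random.default_rng(1).random((1, 8, 16, 16)).astype(np.float32))
        assert out.shape == (1, 16, 16, 16)

    def test_out_channels_must_divide_by_four(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            InceptionBlock(8, 10, np.random.default_rng(0))

    def test_cheaper_than_dense_3x3_convolution(self):
        # 64 -> 64: a single 3x3 conv has 3*3*64*64 = 36864 weights (+64 bias)
        block = InceptionBlock(64, 64, np.random.default_rng(0), batchnorm=False)
        assert count_parameters(block) < 36864


class TestPyramidPooling:
    def test_output_spatial_size_equals_input(self):
        rng = np.random.default_rng(0)
        for pools in [(1, 2, 4, 8), (1, 3), (2,)]:
            ppm = PyramidPooling(8, 12, rng, pool_sizes=pools)
            out = ppm(np.random.default_rng(1).random((1, 8, 16, 16)).astype(np.float32))
            assert out.shape == (1, 12, 16, 16)

    def test_adaptive_pool_computes_quadrant_means(self):
        x = Tensor(np.arange(64, dtype=np.float64).reshape(1, 1, 8, 8))
        out = F.adaptive_avg_pool2d(x, 2).data[0, 0]
        grid = np.arange(64).reshape(8, 8)
        expected = np.array([
            [grid[:4, :4].mean(), grid[:4, 4:].mean()],
            [grid[4:, :4].mean(), grid[4:, 4:].mean()],
        ])
        np.testing.assert_allclose(out, expected)

    def test_unit_pool_branch_propagates_constants(self):
        # global (1x1) pooling of a constant map, upsampled back, is constant
        x = Tensor(np.full((1, 3, 8, 8), 1.7))
        pooled = F.adaptive_avg_pool2d(x, 1)
        np.testing.assert_allclose(pooled.data, 1.7)
        up = F.upsample_bilinear(pooled, (8, 8))
        np.testing.assert_allclose(up.data, 1.7)


def test_se_block_module_keeps_shape_and_mixes_channels():
    block = SEBlock(8, np.random.default_rng(2), ratio=16)  # bottleneck max(1, 8//16) = 1
    # intensities bounded away from zero so the per-channel ratio is well defined
    x = (np.random.default_rng(3).random((2, 8, 4, 4)) + 0.5).astype(np.float64)
    out = block(x)
    assert out.shape == x.shape
    ratio = out.data / x
    per_channel = np.broadcast_to(ratio.mean(axis=(2, 3), keepdims=True), ratio.shape)
    np.testing.assert_allclose(ratio, per_channel, atol=1e-9)
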