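"""Unit tests for the five architectural building blocks."""

import numpy as np
import pytest

from manet.blocks import (AttentionGate, DACBlock, DownFusionPyramid, RMPBlock,
                          ResidualBlock, UpFusion, down_fusion_pyramid, up_fusion)
from manet.engine import Tensor, seeded_init
from manet.errors import InvalidInputError, InvalidSpecError
from manet.spec import NetworkSpec


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestResidualBlock:
    def test_identity_shortcut_when_channels_match(self, rng):
        blk = ResidualBlock(8, 8)
        assert blk.uses_identity_shortcut
        out = blk(rng.random((2, 8, 16, 16), dtype=np.float32))
        assert out.shape == (2, 8, 16, 16)

    def test_projection_shortcut_when_channels_change(self, rng):
        blk = ResidualBlock(3, 8)
        assert not blk.uses_identity_shortcut
        out = blk(rng.random((2, 3, 16, 16), dtype=np.float32))
        assert out.shape == (2, 8, 16, 16)

    def test_zero_transform_reduces_to_shortcut(self, rng):
        x = rng.random((2, 8, 12, 12), dtype=np.float32)
        blk = ResidualBlock(8, 8)
        blk.conv1.weight.data[...] = 0.0
        blk.conv2.weight.data[...] = 0.0
        np.testing.assert_array_equal(blk(x).data, x)

        blk2 = ResidualBlock(8, 4)
        blk2.conv1.weight.data[...] = 0.0
        blk2.conv2.weight.data[...] = 0.0
        expected = blk2.shortcut(Tensor(x)).data
        np.testing.assert_array_equal(blk2(x).data, expected)

    def test_invalid_out_channels_rejected(self):
        with pytest.raises((InvalidSpecError, ValueError)):
            ResidualBlock(4, 0)


class TestAttentionGate:
    def test_output_shape_equals_skip(self, rng):
        gate = AttentionGate(8, 16)
        skip = rng.random((2, 8, 16, 16), dtype=np.float32)
        g = rng.random((2, 16, 8, 8), dtype=np.float32)
        assert gate(skip, g).shape == (2, 8, 16, 16)

    def test_attention_weights_lie_in_unit_interval(self, rng):
        gate = AttentionGate(4, 8)
        alpha = gate.attention_map(rng.standard_normal((1, 4, 8, 8)),
                                   rng.standard_normal((1, 8, 4, 4))).data
        assert alpha.shape == (1, 1, 8, 8)
        assert (alpha >= 0).all() and (alpha <= 1).all()

    def test_saturated_gate_passes_or_suppresses(self, rng):
        skip = rng.random((1, 4, 8, 8), dtype=np.float32)
        g = rng.random((1, 8, 4, 4), dtype=np.float32)
        gate = AttentionGate(4, 8)
        gate.psi.weight.data[...] = 0.0
        gate.psi.bias.data[...] = 50.0  # sigmoid -> 1: output equals skip
        np.testing.assert_allclose(gate(skip, g).data, skip, atol=1e-6)
        gate.psi.bias.data[...] = -50.0  # sigmoid -> 0: full suppression
        np.testing.assert_allclose(gate(skip, g).data, 0.0, atol=1e-6)

    def test_wrong_spatial_ratio_rejected(self, rng):
        gate = AttentionGate(4, 8)
        with pytest.raises(InvalidInputError):
            gate(rng.random((1, 4, 8, 8)), rng.random((1, 8, 8, 8)))


class TestDACBlock:
    def test_preserves_shape(self, rng):
        x = rng.random((1, 6, 12, 12), dtype=np.float32)
        assert DACBlock(6)(x).shape == x.shape

    def test_zero_branches_leave_input_unchanged(self, rng):
        x = rng.random((1, 6, 9, 9), dtype=np.float32)
        blk = DACBlock(6)
        _zero_params(blk)
        np.testing.assert_array_equal(blk(x).data, x)

    def test_single_pixel_input_matches_center_tap_oracle(self, rng):
        # On a 1x1 map every same-padded 3x3 conv reduces to its center tap.
        C = 5
        x = rng.standard_normal((1, C, 1, 1))
        blk = DACBlock(C)
        expected = x.copy()
        for branch in blk.branches:
            v = x[0, :, 0, 0]
            for conv in branch:
                wd = conv.weight.data.astype(np.float64)
                k = wd.shape[-1]
                center = wd[:, :, k // 2, k // 2]
                v = center @ v + conv.bias.data
                v = np.maximum(v, 0.0)
            expected[0, :, 0, 0] += v
        np.testing.assert_allclose(blk(x).data, expected, rtol=1e-5, atol=1e-6)


class TestRMPBlock:
    def test_preserves_shape(self, rng):
        x = rng.random((1, 6, 12, 12), dtype=np.float32)
        assert RMPBlock(6)(x).shape == x.shape

    def test_constant_input_yields_constant_output(self):
        x = np.full((1, 3, 12, 12), 0.7, dtype=np.float32)
        out = RMPBlock(3)(x).data
        np.testing.assert_allclose(out - out[:, :, :1, :1], 0.0, atol=1e-6)

    def test_small_input_rejected_without_clamping(self, rng):
        with pytest.raises(InvalidInputError):
            RMPBlock(3)(rng.random((1, 3, 4, 4)))

    def test_clamped_kernels_allow_small_bottlenecks(self, rng):
        out = RMPBlock(3, clamp_kernels=True)(rng.random((1, 3, 4, 4)))
        assert out.shape == (1, 3, 4, 4)


class TestDownFusionPyramid:
    def test_level_dims_halve_and_channels_double(self, rng):
        spec = NetworkSpec(base_width=8)
        levels = down_fusion_pyramid(rng.random((1, 3, 16, 16), dtype=np.float32), spec)
        shapes = [tuple(lv.shape) for lv in levels]
        assert shapes == [(1, 8, 8, 8), (1, 16, 4, 4), (1, 32, 2, 2), (1, 64, 1, 1)]

    def test_indivisible_input_rejected(self):
        pyramid = DownFusionPyramid(3, 8)
        with pytest.raises(InvalidInputError):
            pyramid(np.zeros((1, 3, 500, 500), dtype=np.float32))


class TestUpFusion:
    def test_deepest_level_gives_empty_bundle(self):
        assert up_fusion([], 4) is None

    def test_single_member_at_level_three(self, rng):
        x4 = rng.random((1, 8, 4, 4), dtype=np.float32)
        bundle = up_fusion([x4], 3)
        assert bundle.shape == (1, 8, 8, 8)

    def test_level_one_concatenates_three_members(self, rng):
        x4 = rng.random((1, 8, 4, 4), dtype=np.float32)
        x3 = rng.random((1, 6, 8, 8), dtype=np.float32)
        x2 = rng.random((1, 4, 16, 16), dtype=np.float32)
        bundle = up_fusion([x4, x3, x2], 1)
        assert bundle.shape == (1, 8 + 6 + 4, 32, 32)

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidInputError):
            up_fusion([], 5)

    def test_zero_weights_give_zero_bundle(self, rng):
        with seeded_init(3):
            fusion = UpFusion([2, 4, 6, 8])
        _zero_params(fusion)
        outs = {4: Tensor(rng.random((1, 8, 2, 2), dtype=np.float32)),
                3: Tensor(rng.random((1, 6, 4, 4), dtype=np.float32))}
        members = fusion(outs, 2)
        assert [m.shape for m in members] == [(1, 8, 8, 8), (1, 6, 8, 8)]
        for m in members:
            np.testing.assert_array_equal(m.data, 0.0)
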