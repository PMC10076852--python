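"""Network blocks: residual unit, CBAM attention, ASPP, receptive field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radunet.blocks import (
    ASPP, ASPPConfig, AttentionConfig, CBAM, ChannelAttention, ResidualBlock,
    SpatialAttention, stacked_receptive_field,
)
from radunet.nn import Tensor, reduce_sum


def zero_params(module):
    for p in module.parameters():
        p.data[:] = 0.0


# -- receptive field ---------------------------------------------------------

class TestReceptiveField:
    def test_dilated_cascade_growth(self):
        """3x3 kernels at rates 1, 2, 4 see 3x3, then 7x7, then 15x15."""
        assert stacked_receptive_field(3, (1,)) == (3,)
        assert stacked_receptive_field(3, (1, 2)) == (3, 7)
        assert stacked_receptive_field(3, (1, 2, 4)) == (3, 7, 15)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            stacked_receptive_field(3, ())
        with pytest.raises(ValueError):
            stacked_receptive_field(4, (1,))
        with pytest.raises(ValueError):
            stacked_receptive_field(3, (0,))

    @given(kernel=st.sampled_from([3, 5, 7]),
           rates=st.lists(st.integers(1, 8), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_kernel_and_rates(self, kernel, rates):
        rf = stacked_receptive_field(kernel, rates)
        assert all(b > a for a, b in zip((1,) + rf, rf))
        bigger_kernel = stacked_receptive_field(kernel + 2, rates)
        assert all(b > a for a, b in zip(rf, bigger_kernel))
        bumped = list(rates)
        bumped[0] += 1
        assert stacked_receptive_field(kernel, bumped)[-1] > rf[-1]


# -- residual block ----------------------------------------------------------

class TestResidualBlock:
    def test_zero_weights_collapse_to_rectified_skip(self, rng):
        blk = ResidualBlock(3, 3, np.random.default_rng(0))
        zero_params(blk)
        x = rng.normal(0, 1, (1, 3, 8, 8)).astype(np.float32)
        out = blk(Tensor(x)).data
        assert np.allclose(out, np.maximum(x, 0.0))

    def test_shape_preserved_and_nonnegative(self, rng):
        blk = ResidualBlock(16, 16, np.random.default_rng(1))
        out = blk(Tensor(rng.normal(0, 1, (2, 16, 32, 32)).astype(np.float32))).data
        assert out.shape == (2, 16, 32, 32)
        assert out.min() >= 0.0

    def test_projection_shortcut_on_channel_change(self, rng):
        blk = ResidualBlock(4, 8, np.random.default_rng(2))
        assert blk.shortcut is not None
        out = blk(Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))).data
        assert out.shape == (1, 8, 8, 8)


# -- attention ---------------------------------------------------------------

class TestChannelAttention:
    def test_zero_mlp_gives_half_weights(self, rng):
        cam = ChannelAttention(AttentionConfig(8, 2), np.random.default_rng(0))
        zero_params(cam)
        w = cam(Tensor(rng.normal(0, 1, (2, 8, 5, 5)).astype(np.float32))).data
        assert w.shape == (2, 8, 1, 1)
        assert np.allclose(w, 0.5)

    def test_spatially_constant_input_doubles_shared_mlp_logit(self):
        """If every pixel of channel c equals v_c, avg- and max-pool agree,
        so the shared MLP fires twice: logits = 2*MLP(v)."""
        cfg = AttentionConfig(2, 1)
        cam = ChannelAttention(cfg, np.random.default_rng(3))
        v = np.array([0.7, -0.4], dtype=np.float32)
        x = np.broadcast_to(v[None, :, None, None], (1, 2, 2, 2)).copy()
        got = cam(Tensor(x)).data[0, :, 0, 0]

        # hand evaluation of the two pooled paths
        w0, b0 = cam.w0.weight.data[:, :, 0, 0], cam.w0.bias.data
        w1, b1 = cam.w1.weight.data[:, :, 0, 0], cam.w1.bias.data
        mlp = w1 @ np.maximum(w0 @ v + b0, 0) + b1
        expected = 1.0 / (1.0 + np.exp(-2.0 * mlp))
        assert np.allclose(got, expected, atol=1e-6)

    def test_weights_strictly_inside_unit_interval(self, rng):
        cam = ChannelAttention(AttentionConfig(4, 4), np.random.default_rng(4))
        w = cam(Tensor(rng.normal(0, 3, (3, 4, 6, 6)).astype(np.float32))).data
        assert np.all((w > 0) & (w < 1))

    def test_channel_count_mismatch_rejected(self, rng):
        cam = ChannelAttention(AttentionConfig(4), np.random.default_rng(0))
        with pytest.raises(ValueError):
            cam(Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32)))


class TestSpatialAttention:
    def test_zero_conv_gives_half_map(self, rng):
        sam = SpatialAttention(AttentionConfig(8), np.random.default_rng(0))
        zero_params(sam)
        w = sam(Tensor(rng.normal(0, 1, (1, 8, 6, 6)).astype(np.float32))).data
        assert w.shape == (1, 1, 6, 6)
        assert np.allclose(w, 0.5)

    @pytest.mark.parametrize("channels", [1, 3, 16])
    def test_output_is_single_channel_map(self, channels, rng):
        sam = SpatialAttention(AttentionConfig(channels), np.random.default_rng(1))
        w = sam(Tensor(rng.normal(0, 1, (2, channels, 9, 9)).astype(np.float32))).data
        assert w.shape == (2, 1, 9, 9)
        assert np.all((w > 0) & (w < 1))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(4, spatial_kernel=6)


class TestCBAM:
    def test_zero_parameters_scale_input_by_quarter(self, rng):
        """Zero logits make both attention stages 0.5, composing to 0.25x."""
        cbam = CBAM(AttentionConfig(4, 2), np.random.default_rng(0))
        zero_params(cbam)
        x = rng.normal(0, 1, (2, 4, 8, 8)).astype(np.float32)
        assert np.allclose(cbam(Tensor(x)).data, 0.25 * x, atol=1e-6)

    def test_attenuates_every_element(self, rng):
        cbam = CBAM(AttentionConfig(4, 2), np.random.default_rng(5))
        x = rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32)
        out = cbam(Tensor(x)).data
        assert out.shape == x.shape
        nonzero = x != 0
        assert np.all(np.abs(out[nonzero]) < np.abs(x[nonzero]))

    def test_shared_mlp_invariance_under_pool_swap(self):
        """With a spatially constant input the avg and max descriptors are
        equal, so which one feeds which MLP call cannot matter — the
        output must equal the doubled single-path evaluation."""
        cfg = AttentionConfig(3, 1)
        cam = ChannelAttention(cfg, np.random.default_rng(6))
        x = np.ones((1, 3, 4, 4), dtype=np.float32) * np.array([1.0, -2.0, 0.5], dtype=np.float32)[None, :, None, None]
        w_once = cam(Tensor(x)).data
        w_twice = cam(Tensor(x.copy())).data
        assert np.array_equal(w_once, w_twice)


# -- ASPP --------------------------------------------------------------------

def brute_force_dilated_conv(x, w, b, rate):
    """Nested-loop direct evaluation of a 'same'-padded dilated 3x3 conv."""
    n, cin, h, wd = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (rate, rate), (rate, rate)))
    out = np.zeros((n, cout, h, wd))
    for ni in range(n):
        for co in range(cout):
            for i in range(h):
                for j in range(wd):
                    acc = b[co]
                    for ci in range(cin):
                        for u in range(3):
                            for v in range(3):
                                acc += w[co, ci, u, v] * xp[ni, ci, i + u * rate, j + v * rate]
                    out[ni, co, i, j] = acc
    return out


class TestASPP:
    def test_five_branches_for_three_rates(self):
        aspp = ASPP(4, ASPPConfig((2, 3, 4), 4), np.random.default_rng(0))
        assert aspp.n_branches == 5

    def test_output_spatial_size_preserved(self, rng):
        aspp = ASPP(4, ASPPConfig((2, 3, 4), 6), np.random.default_rng(1))
        out = aspp(Tensor(rng.normal(0, 1, (2, 4, 16, 16)).astype(np.float32))).data
        assert out.shape == (2, 6, 16, 16)

    @pytest.mark.parametrize("rate", [2, 3, 4, 6])
    def test_dilated_branch_matches_nested_loop_oracle(self, rate, rng):
        aspp = ASPP(2, ASPPConfig((rate,), 3), np.random.default_rng(rate))
        branch = aspp.dilated[0]
        # one-hot and random inputs on a small grid
        for x in (np.eye(9 * 9, dtype=np.float32)[17].reshape(1, 1, 9, 9).repeat(2, 1),
                  rng.normal(0, 1, (1, 2, 9, 9)).astype(np.float32)):
            got = branch(Tensor(x)).data
            want = brute_force_dilated_conv(
                x.astype(np.float64), branch.weight.data.astype(np.float64),
                branch.bias.data.astype(np.float64), rate)
            assert np.allclose(got, want, atol=1e-5)

    def test_rates_must_be_distinct_positive(self):
        with pytest.raises(ValueError):
            ASPPConfig((2, 2, 4), 8)
        with pytest.raises(ValueError):
            ASPPConfig((0,), 8)
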