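"""RAD-UNet assembly: structure, shapes, DFCF wiring, gradient flow."""

import numpy as np
import pytest

from radunet.blocks import AttentionConfig
from radunet.model import (
    DFCF, RADUNet, RADUNetConfig, build_radunet, load_checkpoint,
    save_checkpoint, segment,
)
from radunet.losses import combined_loss
from radunet.nn import Tensor


class TestAssembly:
    def test_exactly_four_dfcf_and_one_aspp(self, tiny_model):
        assert tiny_model.n_dfcf == 4
        assert tiny_model.n_aspp == 1

    @pytest.mark.parametrize("side", [64, 128])
    def test_forward_preserves_spatial_size_with_probabilities(self, tiny_model, side, rng):
        x = rng.random((1, 1, side, side)).astype(np.float32)
        out = tiny_model.forward(Tensor(x)).data
        assert out.shape == (1, 1, side, side)
        assert np.all((out > 0) & (out < 1))

    def test_indivisible_input_side_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.forward(Tensor(rng.random((1, 1, 60, 60)).astype(np.float32)))

    def test_build_is_deterministic_for_fixed_seed(self, tiny_config, rng):
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        a = build_radunet(tiny_config).forward(Tensor(x)).data
        b = build_radunet(tiny_config).forward(Tensor(x)).data
        assert np.array_equal(a, b)
        assert build_radunet(tiny_config).n_parameters() == build_radunet(tiny_config).n_parameters()

    def test_plain_unet_reduction_keeps_topology(self, rng):
        """Disabling residual blocks and attention yields a standard U-Net:
        same stage count and skip wiring, smaller parameter count."""
        base = RADUNetConfig(base_channels=2, attention_reduction=2, seed=0)
        plain_cfg = RADUNetConfig(base_channels=2, attention_reduction=2, seed=0,
                                  residual_encoder=False, use_attention=False)
        full, plain = build_radunet(base), build_radunet(plain_cfg)
        assert len(plain.encoder_stages) == len(full.encoder_stages) == 4
        assert len(plain.decoder_stages) == len(full.decoder_stages) == 4
        assert plain.n_dfcf == 0
        out = plain.forward(Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))).data
        assert out.shape == (1, 1, 32, 32)

    def test_every_parameter_receives_gradient(self, rng):
        cfg = RADUNetConfig(base_channels=2, attention_reduction=2, seed=3)
        model = build_radunet(cfg)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        y = (rng.random((2, 1, 32, 32)) < 0.1).astype(np.float32)
        loss = combined_loss(y, model.forward(Tensor(x)))
        loss.backward()
        dead = [i for i, p in enumerate(model.parameters())
                if p.grad is None or not np.any(p.grad)]
        assert dead == [], f"parameters with zero gradient: {dead}"


class TestDFCF:
    @pytest.fixture
    def streams(self, rng):
        lsf = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
        gsf = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
        return lsf, gsf

    def _dfcf(self, combine="concat", sam_source="self"):
        cfg = RADUNetConfig(base_channels=4, attention_reduction=2,
                            dfcf_combine=combine, dfcf_sam_source=sam_source, seed=0)
        return DFCF(4, cfg, np.random.default_rng(0))

    def test_identical_streams_give_identical_branches(self, rng):
        fuse = self._dfcf(combine="sum")
        f = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
        a = fuse._branch(f, f).data
        b = fuse._branch(f, f).data
        assert np.array_equal(a, b)

    def test_zero_parameters_sum_combine_halves_input(self, rng):
        fuse = self._dfcf(combine="sum")
        for p in fuse.parameters():
            p.data[:] = 0.0
        f = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
        out = fuse(f, f).data
        assert np.allclose(out, 0.5 * f.data, atol=1e-6)

    def test_output_shape_preserved(self, streams):
        lsf, gsf = streams
        for combine in ("concat", "sum"):
            assert self._dfcf(combine)(lsf, gsf).shape == lsf.shape

    def test_cross_wiring_is_mandatory(self, streams):
        """Channel weights must come from the opposite stream: changing only
        the LSF must change branch A's weights applied to the GSF."""
        lsf, gsf = streams
        fuse = self._dfcf(combine="sum")
        out1 = fuse(lsf, gsf).data
        lsf2 = Tensor(lsf.data * np.float32(-1.5))
        out2 = fuse(lsf2, gsf).data
        assert not np.allclose(out1, out2)

    def test_sam_source_other_is_selectable(self, streams):
        lsf, gsf = streams
        a = self._dfcf(sam_source="self")(lsf, gsf).data
        b = self._dfcf(sam_source="other")(lsf, gsf).data
        assert a.shape == b.shape
        assert not np.allclose(a, b)

    def test_shape_mismatch_rejected(self, rng):
        fuse = self._dfcf()
        with pytest.raises(ValueError):
            fuse(Tensor(np.zeros((1, 4, 8, 8), np.float32)),
                 Tensor(np.zeros((1, 4, 4, 4), np.float32)))


class TestSegment:
    def test_threshold_monotonicity(self, tiny_model, phantom_sample):
        masks = [segment(tiny_model, phantom_sample.image, t) for t in (0.3, 0.5, 0.7)]
        assert masks[0].sum() >= masks[1].sum() >= masks[2].sum()

    def test_constant_probability_maps(self, tiny_model, monkeypatch):
        monkeypatch.setattr(tiny_model.__class__, "predict_proba",
                            lambda self, img: np.full(img.shape, 0.7, np.float32))
        assert segment(tiny_model, np.zeros((32, 32)), 0.5).all()
        monkeypatch.setattr(tiny_model.__class__, "predict_proba",
                            lambda self, img: np.full(img.shape, 0.3, np.float32))
        assert not segment(tiny_model, np.zeros((32, 32)), 0.5).any()

    def test_unnormalized_input_warns_and_clips(self, tiny_model):
        with pytest.warns(UserWarning, match="not normalized"):
            segment(tiny_model, np.full((32, 32), 900.0), 0.5)

    def test_invalid_threshold_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            segment(tiny_model, np.zeros((32, 32)), 0.0)


class TestCheckpoint:
    def test_roundtrip_bit_identical(self, tiny_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_model)
        restored = load_checkpoint(path)
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(tiny_model.forward(Tensor(x)).data,
                              restored.forward(Tensor(x)).data)
        assert restored.cfg == tiny_model.cfg
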