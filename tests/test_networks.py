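"""Architecture construction: schedules, blocks, gates, VAE branch, heads."""

import numpy as np
import pytest

from glioseg.networks import (AttentionGate, ConvBlock, NetworkConfig, UNet3D,
                              build_network, channel_schedule, residual_wrap)
from glioseg.nn import Tensor, no_grad


class TestChannelSchedule:
    @pytest.mark.parametrize("depth,base,cap,expected", [
        (7, 64, 512, [64, 128, 256, 512, 512, 512, 512]),
        (6, 32, 320, [32, 64, 128, 256, 320, 320]),
        (2, 8, 8, [8, 8]),
    ])
    def test_doubling_with_cap(self, depth, base, cap, expected):
        cfg = NetworkConfig(depth=depth, base_channels=base, channel_cap=cap)
        assert channel_schedule(cfg) == expected

    def test_schedule_is_nondecreasing_and_capped(self):
        cfg = NetworkConfig(depth=7, base_channels=96, channel_cap=512)
        sched = channel_schedule(cfg)
        assert sched == sorted(sched) and max(sched) == 512 and sched[0] == 96


class TestConvBlock:
    def test_stride_two_halves_extent(self, rng):
        block = ConvBlock(8, 16, 2, rng)
        out = block(Tensor(rng.normal(size=(1, 8, 16, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 16, 8, 8, 8)

    def test_stride_one_preserves_extent(self, rng):
        block = ConvBlock(8, 8, 1, rng)
        out = block(Tensor(rng.normal(size=(1, 8, 16, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 8, 16, 16, 16)

    def test_zero_input_stays_finite(self, rng):
        block = ConvBlock(4, 4, 1, rng)
        out = block(Tensor(np.zeros((1, 4, 8, 8, 8), dtype=np.float32)))
        assert np.isfinite(out.data).all()

    def test_invalid_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ConvBlock(0, 4, 1, rng)


class TestResidualWrap:
    class _Zero:
        def __call__(self, x):
            return x * 0.0

    def test_zero_block_returns_shortcut(self, rng):
        wrapped = residual_wrap(self._Zero(), 4, 4, 1, rng)
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(wrapped(x).data, x.data)

    def test_matched_channels_identity_shortcut(self, rng):
        wrapped = residual_wrap(self._Zero(), 4, 4, 1, rng)
        assert wrapped.projection is None

    def test_mismatched_channels_get_projection(self, rng):
        block = ConvBlock(4, 8, 1, rng)
        wrapped = residual_wrap(block, 4, 8, 1, rng)
        assert wrapped.projection is not None
        x = Tensor(rng.normal(size=(1, 4, 6, 6, 6)).astype(np.float32))
        assert wrapped(x).shape == (1, 8, 6, 6, 6)


class TestAttentionGate:
    def test_coefficients_in_unit_interval(self, rng):
        gate = AttentionGate(8, 16, rng)
        skip = Tensor(rng.normal(size=(1, 8, 8, 8, 8)).astype(np.float32))
        gating = Tensor(rng.normal(size=(1, 16, 4, 4, 4)).astype(np.float32))
        alpha = gate.coefficients(skip, gating).data
        assert alpha.shape == (1, 1, 8, 8, 8)
        assert (alpha > 0).all() and (alpha < 1).all()

    def test_saturated_bias_gives_identity_or_zero(self, rng):
        gate = AttentionGate(4, 4, rng)
        skip = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
        gating = Tensor(rng.normal(size=(1, 4, 2, 2, 2)).astype(np.float32))
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 40.0          # sigmoid saturates to 1
        np.testing.assert_allclose(gate(skip, gating).data, skip.data, atol=1e-6)
        gate.psi.bias.data[:] = -40.0         # sigmoid saturates to 0
        np.testing.assert_allclose(gate(skip, gating).data, 0.0, atol=1e-6)

    def test_incompatible_extents_rejected(self, rng):
        gate = AttentionGate(4, 4, rng)
        skip = Tensor(np.zeros((1, 4, 8, 8, 8), dtype=np.float32))
        gating = Tensor(np.zeros((1, 4, 3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError):
            gate(skip, gating)


class TestVAEBranch:
    def _net(self):
        cfg = NetworkConfig(variant="ae_unet", depth=3, base_channels=4,
                            channel_cap=16, latent_dim=16)
        return cfg, build_network(cfg, 0)

    def test_reconstruction_shape_matches_input(self, rng):
        cfg, net = self._net()
        x = rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32)
        with no_grad():
            out = net.forward(x, rng=np.random.default_rng(0))
        assert out.reconstruction.shape == (1, 4, 8, 8, 8)
        assert out.mu.shape == (1, 16) and out.log_var.shape == (1, 16)

    def test_sampling_is_seed_deterministic(self, rng):
        cfg, net = self._net()
        x = rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32)
        with no_grad():
            a = net.forward(x, rng=np.random.default_rng(5)).reconstruction.data
            b = net.forward(x, rng=np.random.default_rng(5)).reconstruction.data
        np.testing.assert_array_equal(a, b)

    def test_no_rng_collapses_to_mean(self, rng):
        """Without sampling noise z = mu (the log_var -> -inf limit)."""
        cfg, net = self._net()
        x = rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32)
        with no_grad():
            mu = net.forward(x).mu
            bottleneck_probe = net.forward(x, rng=None).reconstruction.data
            again = net.forward(x, rng=None).reconstruction.data
        np.testing.assert_array_equal(bottleneck_probe, again)

    def test_other_variants_have_no_vae(self):
        cfg = NetworkConfig(variant="unet", depth=3, base_channels=4, channel_cap=8)
        net = build_network(cfg, 0)
        assert net.vae is None
        with no_grad():
            out = net.forward(np.zeros((1, 4, 8, 8, 8), dtype=np.float32))
        assert out.reconstruction is None


class TestForwardShapes:
    @pytest.mark.parametrize("variant", ["unet", "res_unet"])
    @pytest.mark.parametrize("deep_supervision", [True, False])
    def test_head_resolutions(self, variant, deep_supervision, rng):
        cfg = NetworkConfig(variant=variant, depth=4, base_channels=4,
                            channel_cap=16, deep_supervision=deep_supervision)
        net = build_network(cfg, 0)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        with no_grad():
            out = net.forward(x)
        expected = [(1, 3, 16 // 2**a, 16 // 2**a, 16 // 2**a)
                    for a in range(cfg.n_heads)]
        assert [tuple(p.shape) for p in out.probs] == expected
        assert len(out.probs) == (3 if deep_supervision else 1)
        for p in out.probs:
            assert (p.data > 0).all() and (p.data < 1).all()

    def test_unet_and_res_unet_shapes_match(self, rng):
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        shapes = []
        for variant in ("unet", "res_unet"):
            cfg = NetworkConfig(variant=variant, depth=3, base_channels=4,
                                channel_cap=8)
            with no_grad():
                out = build_network(cfg, 0).forward(x)
            shapes.append([tuple(p.shape) for p in out.probs])
        assert shapes[0] == shapes[1]

    def test_depth7_bottleneck_on_128_patch_is_2(self):
        """Depth-7 encoder reduces a 128³ patch to a 2³ bottleneck."""
        cfg = NetworkConfig(depth=7)
        assert 128 // 2 ** (cfg.depth - 1) == 2

    def test_odd_input_padded_and_cropped(self, rng):
        cfg = NetworkConfig(variant="unet", depth=3, base_channels=4, channel_cap=8)
        net = build_network(cfg, 0)
        x = rng.normal(size=(1, 4, 10, 9, 11)).astype(np.float32)
        with no_grad():
            out = net.forward(x)
        assert tuple(out.probs[0].shape) == (1, 3, 10, 9, 11)
        assert tuple(out.probs[1].shape) == (1, 3, 5, 5, 6)   # ceil rule

    def test_wrong_channel_count_rejected(self):
        net = build_network(NetworkConfig(variant="unet", depth=2, base_channels=4,
                                          channel_cap=4), 0)
        with pytest.raises(ValueError, match="channels"):
            net.forward(np.zeros((1, 3, 8, 8, 8), dtype=np.float32))


class TestGradientFlow:
    @pytest.mark.parametrize("variant", ["unet", "res_unet", "attention_unet",
                                         "ae_unet"])
    def test_every_parameter_receives_gradient(self, variant, rng):
        from glioseg.losses import LossConfig, deep_supervision_loss, vae_loss
        cfg = NetworkConfig(variant=variant, depth=3, base_channels=4,
                            channel_cap=8, latent_dim=8)
        net = build_network(cfg, 0)
        x = rng.normal(size=(2, 4, 8, 8, 8)).astype(np.float32)
        y = (rng.random((2, 3, 8, 8, 8)) < 0.3).astype(np.float32)
        out = net.forward(x, rng=np.random.default_rng(0) if variant == "ae_unet" else None)
        loss = deep_supervision_loss(out.probs, y, LossConfig())
        if variant == "ae_unet":
            loss = loss + vae_loss(out.reconstruction, x, out.mu, out.log_var,
                                   LossConfig())
        loss.backward()
        missing = [name for name, p in net.named_parameters() if p.grad is None
                   or not np.any(p.grad)]
        assert missing == []


class TestConfigValidation:
    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            NetworkConfig(variant="transformer")

    def test_depth_too_small(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=1)

    def test_n_heads_bounded_by_depth(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=3, n_heads=3)
        assert NetworkConfig(depth=3).n_heads == 2    # clamped default
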