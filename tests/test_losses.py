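"""Loss oracles: batch Dice, BCE, focal, composite, deep supervision, VAE."""

import numpy as np
import pytest

from glioseg.losses import (LossConfig, combined_loss, deep_supervision_loss,
                            dice_loss, secondary_loss, vae_loss)


def brute_dice_channel(p, t, smooth):
    """Direct evaluation of 1 - (2 Σpt + s)/(Σp + Σt + s) per channel."""
    losses = []
    for c in range(p.shape[1]):
        pc, tc = p[:, c].ravel(), t[:, c].ravel()
        losses.append(1 - (2 * (pc * tc).sum() + smooth) / (pc.sum() + tc.sum() + smooth))
    return float(np.mean(losses))


def make_pair(rng, shape=(2, 3, 4, 4, 4)):
    p = rng.random(shape)
    t = (rng.random(shape) < 0.3).astype(float)
    return p, t


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        t = np.zeros((1, 3, 4, 4, 4))
        t[:, :, :2] = 1.0
        assert float(dice_loss(t, t)) < 1e-4

    def test_disjoint_masks_near_one(self):
        p = np.zeros((1, 3, 4, 4, 4))
        t = np.zeros((1, 3, 4, 4, 4))
        p[:, :, 0], t[:, :, 1] = 1.0, 1.0
        assert float(dice_loss(p, t)) > 0.999

    def test_half_overlap_is_half(self):
        # pred {2 voxels}, target {2 voxels}, 1 shared -> Dice 0.5
        p = np.zeros((1, 3, 2, 2, 2))
        t = np.zeros((1, 3, 2, 2, 2))
        p[:, :, 0, 0, 0] = p[:, :, 0, 0, 1] = 1.0
        t[:, :, 0, 0, 1] = t[:, :, 0, 1, 0] = 1.0
        cfg = LossConfig(smooth=1e-12)
        assert float(dice_loss(p, t, cfg)) == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_on_random_tensors(self, rng):
        p, t = make_pair(rng)
        cfg = LossConfig()
        want = brute_dice_channel(p, t, cfg.smooth)
        assert float(dice_loss(p, t, cfg)) == pytest.approx(want, abs=1e-6)

    def test_batch_form_equals_per_item_on_identical_items(self, rng):
        p1, t1 = make_pair(rng, (1, 3, 3, 3, 3))
        p = np.concatenate([p1, p1]); t = np.concatenate([t1, t1])
        batch = float(dice_loss(p, t, LossConfig(batch_dice=True)))
        per_item = float(dice_loss(p, t, LossConfig(batch_dice=False)))
        assert batch == pytest.approx(per_item, abs=1e-6)

    def test_monotone_in_overlap_by_enumeration(self):
        """Sliding a fixed-size mask toward the target never raises the loss."""
        t = np.zeros((1, 1, 1, 1, 8)); t[..., 0:4] = 1.0
        cfg = LossConfig(smooth=1e-12)
        prev = np.inf
        for shift in (4, 3, 2, 1, 0):      # overlap grows 0 -> 4
            p = np.zeros_like(t); p[..., shift:shift + 4] = 1.0
            cur = float(dice_loss(np.repeat(p, 3, 1), np.repeat(t, 3, 1), cfg))
            assert cur <= prev + 1e-12
            prev = cur

    def test_rejects_out_of_range_probs(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((1, 3, 2, 2, 2), 1.5), np.ones((1, 3, 2, 2, 2)))


class TestSecondaryLoss:
    def test_focal_gamma_zero_equals_bce(self, rng):
        p, t = make_pair(rng)
        bce = float(secondary_loss(p, t, LossConfig(secondary="bce")))
        focal0 = float(secondary_loss(p, t, LossConfig(secondary="focal", gamma=0.0)))
        assert focal0 == pytest.approx(bce, rel=1e-6)

    def test_perfect_prediction_zero(self):
        t = (np.arange(24).reshape(1, 3, 2, 2, 2) % 2).astype(float)
        assert float(secondary_loss(t, t, LossConfig(secondary="focal"))) < 1e-5
        assert float(secondary_loss(t, t, LossConfig(secondary="bce"))) < 1e-5

    def test_focal_hand_computed_value(self):
        # single voxel p=0.5, t=1, gamma=2: (1-0.5)^2 * -log(0.5) = 0.25 ln 2
        p = np.full((1, 1, 1, 1, 1), 0.5)
        t = np.ones((1, 1, 1, 1, 1))
        got = float(secondary_loss(p, t, LossConfig(secondary="focal", gamma=2.0)))
        assert got == pytest.approx(0.25 * np.log(2), rel=1e-6)

    def test_bce_matches_direct_formula(self, rng):
        p, t = make_pair(rng)
        pc = np.clip(p, 1e-7, 1 - 1e-7)
        want = float(np.mean(-(t * np.log(pc) + (1 - t) * np.log(1 - pc))))
        got = float(secondary_loss(p, t, LossConfig(secondary="bce")))
        assert got == pytest.approx(want, rel=1e-6)


class TestCombinedLoss:
    def test_alpha_limits(self, rng):
        p, t = make_pair(rng)
        cfg1 = LossConfig(alpha=1.0)
        cfg0 = LossConfig(alpha=0.0)
        assert float(combined_loss(p, t, cfg1)) == pytest.approx(
            float(dice_loss(p, t, cfg1)), rel=1e-6)
        assert float(combined_loss(p, t, cfg0)) == pytest.approx(
            float(secondary_loss(p, t, cfg0)), rel=1e-6)

    def test_alpha_07_is_convex_combination(self, rng):
        p, t = make_pair(rng)
        cfg = LossConfig(alpha=0.7)
        d = float(dice_loss(p, t, cfg))
        s = float(secondary_loss(p, t, cfg))
        assert float(combined_loss(p, t, cfg)) == pytest.approx(0.7 * d + 0.3 * s, rel=1e-6)

    def test_linear_in_alpha(self, rng):
        p, t = make_pair(rng)
        vals = [float(combined_loss(p, t, LossConfig(alpha=a)))
                for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        # second differences of a linear function vanish
        second = np.diff(vals, n=2)
        assert np.abs(second).max() < 1e-9


class TestDeepSupervision:
    def _heads_and_target(self, rng):
        t = (rng.random((1, 3, 8, 8, 8)) < 0.3).astype(float)
        heads = [rng.random((1, 3, 8 // 2**a, 8 // 2**a, 8 // 2**a)) for a in range(3)]
        return heads, t

    def test_equal_weights_average_per_head_losses(self, rng):
        heads, t = self._heads_and_target(rng)
        cfg = LossConfig()
        per_head = [float(combined_loss(h, t[:, :, ::2**a, ::2**a, ::2**a], cfg))
                    for a, h in enumerate(heads)]
        got = float(deep_supervision_loss(heads, t, cfg))
        assert got == pytest.approx(np.mean(per_head), rel=1e-6)

    def test_single_head_equals_combined(self, rng):
        heads, t = self._heads_and_target(rng)
        cfg = LossConfig()
        got = float(deep_supervision_loss(heads[:1], t, cfg))
        assert got == pytest.approx(float(combined_loss(heads[0], t, cfg)), rel=1e-6)

    def test_weights_w00_select_final_head(self, rng):
        heads, t = self._heads_and_target(rng)
        cfg = LossConfig(head_weights=(2.0, 0.0, 0.0))
        got = float(deep_supervision_loss(heads, t, cfg))
        assert got == pytest.approx(float(combined_loss(heads[0], t, LossConfig())),
                                    rel=1e-6)

    def test_exact_heads_give_zero(self, rng):
        t = (rng.random((1, 3, 8, 8, 8)) < 0.3).astype(float)
        heads = [t[:, :, ::2**a, ::2**a, ::2**a] for a in range(3)]
        assert float(deep_supervision_loss(heads, t)) < 1e-3

    def test_head_weight_count_mismatch(self, rng):
        heads, t = self._heads_and_target(rng)
        with pytest.raises(ValueError):
            deep_supervision_loss(heads, t, LossConfig(head_weights=(1.0, 1.0)))


class TestVAELoss:
    def test_standard_normal_has_zero_kl(self, rng):
        x = rng.random((1, 4, 4, 4, 4))
        cfg = LossConfig(vae_weight_rec=0.0, vae_weight_kl=1.0)
        got = float(vae_loss(x, x, np.zeros((1, 8)), np.zeros((1, 8)), cfg))
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_perfect_reconstruction_zero_rec_term(self, rng):
        x = rng.random((1, 4, 4, 4, 4))
        cfg = LossConfig(vae_weight_rec=1.0, vae_weight_kl=0.0)
        assert float(vae_loss(x, x, rng.normal(size=(1, 8)),
                              np.zeros((1, 8)), cfg)) == pytest.approx(0.0, abs=1e-9)

    def test_unit_mean_single_dim_kl_half(self):
        # closed form: KL = 0.5 (e^0 + 1 - 1 - 0) ... mu=(1,0,..,0), logvar=0 -> 0.5
        mu = np.zeros((1, 8)); mu[0, 0] = 1.0
        cfg = LossConfig(vae_weight_rec=0.0, vae_weight_kl=1.0)
        x = np.zeros((1, 2, 2, 2, 2))
        assert float(vae_loss(x, x, mu, np.zeros((1, 8)), cfg)) == pytest.approx(0.5)

    def test_non_finite_latents_rejected(self):
        x = np.zeros((1, 2, 2, 2, 2))
        with pytest.raises(ValueError):
            vae_loss(x, x, np.array([[np.nan]]), np.array([[0.0]]))


class TestLossConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.5}, {"secondary": "hinge"}, {"gamma": -1},
        {"smooth": 0.0}, {"head_weights": (0.0, 0.0)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossConfig(**kwargs)
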