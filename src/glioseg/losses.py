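"""Composite segmentation losses: batch Dice, BCE/focal, deep supervision, VAE.

The training objective is a convex combination

    L = α · Dice + (1 − α) · secondary,        α ∈ [0, 1], default 0.7

where the Dice term uses the *batch* form — intersection and mask sums are
pooled over every item in the batch before the ratio is taken, one ratio
per region channel — and the secondary term is voxel-wise binary
cross-entropy or focal loss. With deep supervision enabled, the combined
loss is evaluated at each auxiliary head against nearest-neighbor
downsampled targets and aggregated as a normalized weighted sum.

All loss functions accept numpy arrays or :class:`glioseg.nn.Tensor`
objects with layout ``(N, C, D, H, W)`` (a missing batch axis is added)
and return a scalar ``Tensor``; use ``float(...)`` for the value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import RegionMask, downsample_volume_nn
from .nn.tensor import Tensor, as_tensor

_EPS = 1e-7  # probability clamp for the logarithmic terms


@dataclass
class LossConfig:
    alpha: float = 0.7
    secondary: str = "focal"            # one of {"bce", "focal"}
    gamma: float = 2.0                  # focal exponent
    smooth: float = 1e-5                # Dice stabilizer
    batch_dice: bool = True
    head_weights: tuple[float, ...] | None = None  # default: equal weights
    vae_weight_kl: float = 0.1
    vae_weight_rec: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.secondary not in ("bce", "focal"):
            raise ValueError(f"secondary loss must be 'bce' or 'focal', got {self.secondary!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")
        if self.head_weights is not None:
            hw = tuple(float(w) for w in self.head_weights)
            if any(w < 0 for w in hw) or not any(w > 0 for w in hw):
                raise ValueError("head_weights must be >= 0 and not all zero")
            self.head_weights = hw


def _as_batched(x) -> Tensor:
    t = as_tensor(x.channels if isinstance(x, RegionMask) else x)
    if t.ndim == 4:
        t = t.reshape((1,) + t.shape)
    if t.ndim != 5:
        raise ValueError(f"expected (N, C, D, H, W) or (C, D, H, W), got shape {t.shape}")
    return t


def _check_pair(probs: Tensor, targets: Tensor):
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    if probs.data.min() < -1e-6 or probs.data.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")


def dice_loss(probs, targets, config: LossConfig | None = None) -> Tensor:
    """Soft Dice loss, averaged over channels, in [0, 1].

    Per channel c:  1 − (2·Σ p·t + s) / (Σ p + Σ t + s), the sums running
    jointly over batch and voxels (``batch_dice``) or per item and then
    averaged.
    """
    config = config or LossConfig()
    p, t = _as_batched(probs), _as_batched(targets)
    _check_pair(p, t)
    axes = (0, 2, 3, 4) if config.batch_dice else (2, 3, 4)
    s = config.smooth
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + s) / (denom + s)
    return 1.0 - dice.mean()


def secondary_loss(probs, targets, config: LossConfig | None = None) -> Tensor:
    """Mean voxel-wise BCE or focal loss, per ``config.secondary``."""
    config = config or LossConfig()
    p, t = _as_batched(probs), _as_batched(targets)
    _check_pair(p, t)
    p_t = (p * t + (1.0 - p) * (1.0 - t)).clip(_EPS, 1.0 - _EPS)
    nll = -p_t.log()
    if config.secondary == "bce":
        return nll.mean()
    return ((1.0 - p_t) ** config.gamma * nll).mean()


def combined_loss(probs, targets, config: LossConfig | None = None) -> Tensor:
    """α·Dice + (1−α)·secondary."""
    config = config or LossConfig()
    return (config.alpha * dice_loss(probs, targets, config)
            + (1.0 - config.alpha) * secondary_loss(probs, targets, config))


def deep_supervision_loss(heads, full_res_targets, config: LossConfig | None = None,
                          return_per_head: bool = False):
    """Aggregate the combined loss over supervision heads A = 1..n.

    ``heads`` is a list of probability tensors at full, 1/2, 1/4, ...
    resolution (head A downsampled by 2^(A−1)); targets for the auxiliary
    heads are obtained from ``full_res_targets`` by nearest-neighbor
    downsampling. Aggregation is Σ w_A L_A / Σ w_A with equal default
    weights.
    """
    config = config or LossConfig()
    heads = list(heads)
    weights = config.head_weights or (1.0,) * len(heads)
    if len(weights) != len(heads):
        raise ValueError(f"{len(heads)} heads but {len(weights)} head weights")
    tgt = full_res_targets.channels if isinstance(full_res_targets, RegionMask) \
        else np.asarray(full_res_targets)
    per_head = []
    total = None
    for a, (head, w) in enumerate(zip(heads, weights)):
        f = 2**a
        target = downsample_volume_nn(tgt, (f, f, f))
        loss_a = combined_loss(head, target, config)
        per_head.append(loss_a)
        term = w * loss_a
        total = term if total is None else total + term
    total = total / sum(weights)
    if return_per_head:
        return total, per_head
    return total


def vae_loss(reconstruction, input_volume, mu, log_var,
             config: LossConfig | None = None) -> Tensor:
    """Regularization terms of the autoencoder branch.

    Mean squared reconstruction error plus the closed-form KL divergence
    KL(N(μ, diag e^logvar) ‖ N(0, I)) = ½ Σ_d (e^logvar + μ² − 1 − logvar),
    averaged over the batch, each weighted by its config coefficient.
    """
    config = config or LossConfig()
    rec, x = as_tensor(reconstruction), as_tensor(input_volume)
    mu, log_var = as_tensor(mu), as_tensor(log_var)
    if not (np.isfinite(mu.data).all() and np.isfinite(log_var.data).all()):
        raise ValueError("non-finite latent statistics")
    if rec.shape != x.shape:
        raise ValueError(f"reconstruction shape {rec.shape} != input shape {x.shape}")
    diff = rec - x
    rec_term = (diff * diff).mean()
    kl_per_item = 0.5 * (log_var.exp() + mu * mu - 1.0 - log_var).sum(axis=-1)
    kl_term = kl_per_item.mean()
    return config.vae_weight_rec * rec_term + config.vae_weight_kl * kl_term
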