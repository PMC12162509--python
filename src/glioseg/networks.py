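"""3D encoder-decoder segmentation networks (U-Net family).

Four variants share one construction path:

* ``unet``            — plain convolutional encoder-decoder
* ``res_unet``        — every conv block carries an identity shortcut
* ``attention_unet``  — additive attention gates reweight the skip features
* ``ae_unet``         — residual blocks plus a variational autoencoder
                        branch off the bottleneck that reconstructs the
                        input (training-time regularization)

Each encoder stage after the first starts with a stride-2 convolution, so a
depth-7 network on a 128³ patch reaches a 2³ bottleneck. The decoder
mirrors the encoder with kernel-2/stride-2 transposed convolutions and
skip concatenation. Output heads are 1³ convolutions with sigmoid, one per
overlapping tumor region (WT, TC, ET); with deep supervision, auxiliary
heads are attached to the next two coarser decoder levels (A = 1..3, head
A at 1/2^(A−1) resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor, concat, no_grad

VARIANTS = ("unet", "res_unet", "attention_unet", "ae_unet")
_RESIDUAL_VARIANTS = ("res_unet", "ae_unet")


@dataclass
class NetworkConfig:
    """Declarative description of a network; fully determines head shapes."""

    variant: str = "res_unet"
    depth: int = 7
    base_channels: int = 64
    channel_cap: int = 512
    in_channels: int = 4
    out_channels: int = 3
    deep_supervision: bool = True
    n_heads: int | None = None          # resolved in __post_init__
    negative_slope: float = 0.01
    latent_dim: int = 256               # ae_unet only
    norm_eps: float = 1e-5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_heads is None:
            self.n_heads = min(3, self.depth - 1) if self.deep_supervision else 1
        if not 1 <= self.n_heads <= self.depth - 1:
            raise ValueError(f"n_heads must be in [1, depth-1], got {self.n_heads}")


def channel_schedule(config: NetworkConfig) -> list[int]:
    """Channels per encoder level: min(base · 2^level, cap).

    Doubling-with-cap covers both common schedules: base 32 / cap 320
    at depth 6 gives 32→320, base 64 / cap 512 at depth 7 gives 64→512.
    """
    return [min(config.base_channels * 2**level, config.channel_cap)
            for level in range(config.depth)]


class ConvBlock(nn.Module):
    """Conv(3³, stride s) → instance norm → LeakyReLU(0.01)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng,
                 negative_slope: float = 0.01, norm_eps: float = 1e-5):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.conv = nn.Conv3d(in_ch, out_ch, 3, rng, stride=stride)
        self.norm = nn.InstanceNorm3d(out_ch, eps=norm_eps)
        self.negative_slope = negative_slope

    def forward(self, x):
        return self.norm(self.conv(x)).leaky_relu(self.negative_slope)


class ResidualWrap(nn.Module):
    """output = block(x) + shortcut(x); identity shortcut when shapes match."""

    def __init__(self, block: nn.Module, projection: nn.Module | None = None):
        self.block = block
        self.projection = projection

    def forward(self, x):
        y = self.block(x)
        s = self.projection(x) if self.projection is not None else x
        return y + s


def residual_wrap(block: nn.Module, in_ch: int, out_ch: int, stride: int,
                  rng) -> ResidualWrap:
    """Add an identity shortcut; a 1³ (strided) projection reconciles shapes."""
    projection = None
    if in_ch != out_ch or stride != 1:
        projection = nn.Conv3d(in_ch, out_ch, 1, rng, stride=stride)
    return ResidualWrap(block, projection)


class AttentionGate(nn.Module):
    """Additive attention: α = σ(ψ(act(Wx·skip + Wg·up(gate)))), α ∈ [0, 1].

    The gating signal comes from the coarser decoder level (half the skip's
    extent) and is nearest-upsampled before mixing; α has a single channel
    and is broadcast-multiplied onto the skip features.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng, negative_slope: float = 0.01):
        inter = max(skip_ch // 2, 1)
        self.theta_x = nn.Conv3d(skip_ch, inter, 1, rng)
        self.phi_g = nn.Conv3d(gate_ch, inter, 1, rng)
        self.psi = nn.Conv3d(inter, 1, 1, rng)
        self.negative_slope = negative_slope

    def coefficients(self, skip, gate) -> Tensor:
        skip, gate = as_tensor(skip), as_tensor(gate)
        if tuple(gate.shape[2:]) != tuple(skip.shape[2:]):
            gate = F.upsample_nearest_x2(gate)
        if tuple(gate.shape[2:]) != tuple(skip.shape[2:]):
            raise ValueError(f"gate extent {gate.shape[2:]} incompatible with "
                             f"skip extent {skip.shape[2:]}")
        mixed = (self.theta_x(skip) + self.phi_g(gate)).leaky_relu(self.negative_slope)
        return self.psi(mixed).sigmoid()

    def forward(self, skip, gate):
        return as_tensor(skip) * self.coefficients(skip, gate)


class VAEBranch(nn.Module):
    """Variational autoencoder head on the bottleneck features.

    The bottleneck is projected to per-channel maps, globally averaged to a
    latent mean/log-variance vector (default 256-dimensional), sampled via
    the reparameterization trick, and decoded by a mirror of the encoder to
    the network input's channel count and (padded) extent.
    """

    def __init__(self, schedule: list[int], in_channels: int, latent_dim: int,
                 rng, negative_slope: float = 0.01):
        bottleneck_ch = schedule[-1]
        self.conv_mu = nn.Conv3d(bottleneck_ch, latent_dim, 1, rng)
        self.conv_log_var = nn.Conv3d(bottleneck_ch, latent_dim, 1, rng)
        dec = [max(c // 4, 4) for c in schedule]
        self.conv_z = nn.Conv3d(latent_dim, dec[-1], 1, rng)
        self.ups = []
        self.blocks = []
        for level in range(len(schedule) - 2, -1, -1):
            self.ups.append(nn.ConvTranspose3d(dec[level + 1], dec[level], rng))
            self.blocks.append(ConvBlock(dec[level], dec[level], 1, rng, negative_slope))
        self.out_conv = nn.Conv3d(dec[0], in_channels, 1, rng)
        self.latent_dim = latent_dim

    def forward(self, bottleneck, rng: np.random.Generator | None = None):
        mu = F.global_mean_pool(self.conv_mu(bottleneck))
        log_var = F.global_mean_pool(self.conv_log_var(bottleneck))
        if rng is not None:
            eps = rng.standard_normal(mu.shape).astype(np.float32)
        else:
            eps = np.zeros(mu.shape, dtype=np.float32)
        z = mu + (log_var * 0.5).exp() * eps
        n, c = z.shape
        grid = z.reshape(n, c, 1, 1, 1) * Tensor(
            np.ones((1, 1) + tuple(bottleneck.shape[2:]), dtype=np.float32))
        h = self.conv_z(grid)
        for up, block in zip(self.ups, self.blocks):
            h = block(up(h))
        return self.out_conv(h), mu, log_var


@dataclass
class HeadOutputs:
    """Sigmoid region probabilities per supervision head (A = 1..n).

    ``probs[a]`` has extent ceil(input_extent / 2^a) per axis; all heads
    share the region channel count. The autoencoder fields are populated
    only for the ``ae_unet`` variant.
    """

    probs: list[Tensor]
    reconstruction: Tensor | None = None
    mu: Tensor | None = None
    log_var: Tensor | None = None

    @property
    def final(self) -> Tensor:
        return self.probs[0]


class UNet3D(nn.Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        sched = channel_schedule(config)
        mk = self._make_block
        self.enc_blocks = []
        for level in range(config.depth):
            if level == 0:
                stage = [mk(config.in_channels, sched[0], 1, rng),
                         mk(sched[0], sched[0], 1, rng)]
            else:
                stage = [mk(sched[level - 1], sched[level], 2, rng),
                         mk(sched[level], sched[level], 1, rng)]
            self.enc_blocks.append(stage)
        self.ups = []
        self.dec_blocks = []
        self.gates = []
        for level in range(config.depth - 2, -1, -1):
            self.ups.append(nn.ConvTranspose3d(sched[level + 1], sched[level], rng))
            self.dec_blocks.append(mk(2 * sched[level], sched[level], 1, rng))
            if config.variant == "attention_unet":
                self.gates.append(AttentionGate(sched[level], sched[level + 1], rng,
                                                config.negative_slope))
        self.heads = [nn.Conv3d(sched[a], config.out_channels, 1, rng)
                      for a in range(config.n_heads)]
        self.vae = None
        if config.variant == "ae_unet":
            self.vae = VAEBranch(sched, config.in_channels, config.latent_dim, rng,
                                 config.negative_slope)

    def _make_block(self, in_ch, out_ch, stride, rng):
        cfg = self.config
        block = ConvBlock(in_ch, out_ch, stride, rng, cfg.negative_slope, cfg.norm_eps)
        if cfg.variant in _RESIDUAL_VARIANTS:
            return residual_wrap(block, in_ch, out_ch, stride, rng)
        return block

    # -- padding ----------------------------------------------------------

    def _pad_spec(self, spatial_shape):
        div = 2 ** (self.config.depth - 1)
        spec = []
        for extent in spatial_shape:
            if extent < 1:
                raise ValueError("input extent must be >= 1 on every axis")
            target = max(-(-extent // div) * div, div)
            before = (target - extent) // 2
            spec.append((before, target - extent - before))
        return spec

    # -- forward ----------------------------------------------------------

    def forward(self, x, rng: np.random.Generator | None = None) -> HeadOutputs:
        x = as_tensor(x)
        if x.ndim == 4:
            x = x.reshape((1,) + x.shape)
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, D, H, W) input, got shape {x.shape}")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels, "
                             f"got {x.shape[1]}")
        orig = tuple(x.shape[2:])
        spec = self._pad_spec(orig)
        if any(b or a for b, a in spec):
            x = Tensor._make(
                np.pad(x.data, ((0, 0), (0, 0)) + tuple(spec)),
                (x,), _make_pad_backward(x, spec))

        skips = []
        h = x
        for stage in self.enc_blocks:
            for block in stage:
                h = block(h)
            skips.append(h)

        dec_feats: dict[int, Tensor] = {}
        h = skips[-1]
        for i, level in enumerate(range(self.config.depth - 2, -1, -1)):
            skip = skips[level]
            if self.gates:
                skip = self.gates[i](skip, h)
            h = self.dec_blocks[i](concat([skip, self.ups[i](h)], axis=1))
            dec_feats[level] = h

        probs = []
        for a, head in enumerate(self.heads):
            p = head(dec_feats[a]).sigmoid()
            probs.append(_crop_head(p, orig, spec, 2**a))

        recon = mu = log_var = None
        if self.vae is not None:
            recon, mu, log_var = self.vae(skips[-1], rng)
            recon = _crop_head(recon, orig, spec, 1)
        return HeadOutputs(probs=probs, reconstruction=recon, mu=mu, log_var=log_var)

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Final-head probabilities for a single (C, D, H, W) volume."""
        with no_grad():
            out = self.forward(np.asarray(volume, dtype=np.float32))
        return out.final.data[0]


def _make_pad_backward(x, spec):
    def backward(g):
        if x.requires_grad:
            sl = (slice(None), slice(None)) + tuple(
                slice(b, g.shape[i + 2] - a) for i, (b, a) in enumerate(spec))
            x._accum(g[sl])
    return backward


def _crop_head(p: Tensor, orig, spec, factor: int) -> Tensor:
    """Crop a head at 1/factor resolution back to ceil(orig / factor)."""
    slices = [slice(None), slice(None)]
    needs_crop = False
    for extent, (before, _after) in zip(orig, spec):
        target = -(-extent // factor)
        start = before // factor
        slices.append(slice(start, start + target))
        if (start, start + target) != (0, p.shape[2 + len(slices) - 3]):
            needs_crop = True
    if not needs_crop:
        return p
    return p[tuple(slices)]


def build_encoder(config: NetworkConfig, rng=None) -> UNet3D:
    """Encoder and decoder are constructed together (the decoder needs the
    encoder's skip channels); both aliases return the assembled network."""
    return build_network(config, rng)


def build_decoder(config: NetworkConfig, rng=None) -> UNet3D:
    """See :func:`build_encoder`; the returned network's forward pass emits
    :class:`HeadOutputs`."""
    return build_network(config, rng)


def build_network(config: NetworkConfig, rng: np.random.Generator | int | None = None) -> UNet3D:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)
    return UNet3D(config, rng)
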