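"""Whole-volume prediction: half-overlap tiling, center weighting, flip TTA.

At inference the input volume may have any extent, so it is tiled with
patch-sized windows whose origins advance by half a patch per axis (the
last window is clamped to end at the volume boundary). Each window's
prediction is blended into the output with a center-peaked Gaussian
importance map — center voxels of a patch are more reliable than its
borders — and the accumulated weighted sum is normalized by the
accumulated weights, which makes the blend exact for constant fields.

Test-time augmentation runs the tiled prediction on all 8 axis-flip
variants of the volume (the subsets of {x, y, z}), un-flips each
probability map, and averages the 8 maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np

from .labels import MultiModalVolume

#: the 8 axis subsets (identity first); axes index (D, H, W)
FLIP_SUBSETS: tuple[tuple[int, ...], ...] = tuple(
    chain.from_iterable(combinations((0, 1, 2), k) for k in range(4)))


@dataclass
class SlidingWindowPlan:
    patch_size: tuple[int, int, int]
    stride: tuple[int, int, int]
    window_origins: list[tuple[int, int, int]]
    pad_spec: tuple[tuple[int, int], ...]           # symmetric pre-padding
    padded_shape: tuple[int, int, int]


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    if patch == extent:
        return [0]
    origins = list(range(0, extent - patch, stride))
    origins.append(extent - patch)                   # clamp the final window
    return origins


def plan_windows(volume_shape, patch_size) -> SlidingWindowPlan:
    """Half-overlap tiling of a (possibly padded) volume.

    Origins per axis are {0, s, 2s, ...} with stride s = patch/2 and the
    final origin clamped so the window ends at the boundary; axes shorter
    than the patch are symmetrically zero-padded first.
    """
    shape = tuple(int(v) for v in volume_shape)
    patch = tuple(int(v) for v in (patch_size if not np.isscalar(patch_size)
                                   else (patch_size,) * 3))
    if len(shape) != 3 or len(patch) != 3:
        raise ValueError("volume_shape and patch_size must be 3D")
    stride = tuple(max(p // 2, 1) for p in patch)
    pad_spec = []
    padded = []
    for extent, p in zip(shape, patch):
        deficit = max(p - extent, 0)
        before = deficit // 2
        pad_spec.append((before, deficit - before))
        padded.append(extent + deficit)
    axis_origins = [_axis_origins(e, p, s) for e, p, s in zip(padded, patch, stride)]
    origins = [(d, h, w) for d in axis_origins[0] for h in axis_origins[1]
               for w in axis_origins[2]]
    return SlidingWindowPlan(patch_size=patch, stride=stride, window_origins=origins,
                             pad_spec=tuple(pad_spec), padded_shape=tuple(padded))


@dataclass
class ImportanceMap:
    """Per-voxel blending weights for one patch; strictly positive."""

    kind: str = "gaussian"
    sigma_fraction: float = 0.125
    floor: float = 1e-3
    weights: np.ndarray = field(default=None, repr=False)

    @classmethod
    def build(cls, patch_size, kind: str = "gaussian",
              sigma_fraction: float = 0.125, floor: float = 1e-3) -> "ImportanceMap":
        patch = tuple(int(v) for v in (patch_size if not np.isscalar(patch_size)
                                       else (patch_size,) * 3))
        if kind == "uniform":
            w = np.ones(patch, dtype=np.float64)
        elif kind == "gaussian":
            axes = []
            for p in patch:
                x = np.arange(p, dtype=np.float64) - (p - 1) / 2.0
                sigma = max(sigma_fraction * p, 1e-9)
                axes.append(np.exp(-0.5 * (x / sigma) ** 2))
            w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
            w = np.maximum(w, floor)
        else:
            raise ValueError(f"unknown importance kind {kind!r}")
        return cls(kind=kind, sigma_fraction=sigma_fraction, floor=floor, weights=w)


def _predict_fn(net):
    if callable(net) and not hasattr(net, "predict"):
        return net
    return net.predict


def sliding_window_predict(net, volume, plan: SlidingWindowPlan | None = None,
                           importance: ImportanceMap | None = None) -> np.ndarray:
    """Weighted overlap-tile prediction; returns (3, D, H, W) probabilities.

    ``net`` is any callable mapping a (C, p, p, p) patch to (3, p, p, p)
    probabilities (e.g. ``UNet3D.predict``). Output voxels are
    Σ_w weight·prob / Σ_w weight over covering windows.
    """
    channels = volume.channels if isinstance(volume, MultiModalVolume) else np.asarray(volume)
    if channels.ndim != 4:
        raise ValueError(f"expected (C, D, H, W) volume, got shape {channels.shape}")
    spatial = channels.shape[1:]
    if plan is None:
        raise ValueError("a SlidingWindowPlan is required (see plan_windows)")
    if importance is None:
        importance = ImportanceMap.build(plan.patch_size)
    if tuple(importance.weights.shape) != tuple(plan.patch_size):
        raise ValueError("importance map shape does not match the patch size")

    padded = np.pad(channels, ((0, 0),) + plan.pad_spec)
    if padded.shape[1:] != plan.padded_shape:
        raise ValueError(f"plan was made for shape {plan.padded_shape}, "
                         f"volume pads to {padded.shape[1:]}")
    predict = _predict_fn(net)
    w = importance.weights
    num = np.zeros((3,) + plan.padded_shape, dtype=np.float64)
    den = np.zeros(plan.padded_shape, dtype=np.float64)
    pd_, ph, pw = plan.patch_size
    for (d, h, ww) in plan.window_origins:
        patch = padded[:, d:d + pd_, h:h + ph, ww:ww + pw]
        probs = np.asarray(predict(patch), dtype=np.float64)
        if probs.shape != (3, pd_, ph, pw):
            raise ValueError(f"network returned shape {probs.shape}, "
                             f"expected {(3, pd_, ph, pw)}")
        if not np.isfinite(probs).all():
            raise ValueError("non-finite network output")
        num[:, d:d + pd_, h:h + ph, ww:ww + pw] += w * probs
        den[d:d + pd_, h:h + ph, ww:ww + pw] += w
    out = num / den
    crop = tuple(slice(b, b + e) for (b, _a), e in zip(plan.pad_spec, spatial))
    out = out[(slice(None),) + crop]
    return np.clip(out, 0.0, 1.0)


def flip_volume(array: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Flip the trailing three spatial axes named by ``axes`` (involution)."""
    if not axes:
        return array
    offset = array.ndim - 3
    return np.flip(array, axis=tuple(a + offset for a in axes))


def tta_predict(net, volume, plan: SlidingWindowPlan | None = None,
                importance: ImportanceMap | None = None,
                flip_subsets=FLIP_SUBSETS) -> np.ndarray:
    """Average tiled predictions over axis-flip variants of the volume.

    For each subset of spatial axes: flip the input, predict, un-flip the
    probability map; the returned map is the arithmetic mean over subsets
    (probabilities are averaged post-sigmoid).
    """
    channels = volume.channels if isinstance(volume, MultiModalVolume) else np.asarray(volume)
    acc = None
    for axes in flip_subsets:
        flipped = flip_volume(channels, tuple(axes))
        pred = sliding_window_predict(net, flipped, plan, importance)
        pred = flip_volume(pred, tuple(axes))
        acc = pred if acc is None else acc + pred
    return acc / len(flip_subsets)
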