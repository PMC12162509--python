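"""Label vocabulary and overlapping region encoding for brain-tumor volumes.

The integer label vocabulary follows the BraTS convention:

====== ==============================================
value  tissue
====== ==============================================
0      background / healthy tissue
1      necrotic and non-enhancing tumor core (NCR)
2      peritumoral edema (ED)
4      enhancing tumor (ET)
====== ==============================================

The networks do not predict these mutually exclusive classes directly;
they predict three *overlapping* regions, each with its own sigmoid
channel, in the fixed order

* WT (whole tumor)     = labels {1, 2, 4}
* TC (tumor core)      = labels {1, 4}
* ET (enhancing tumor) = labels {4}

so ET ⊆ TC ⊆ WT at every voxel (the nesting invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_LABELS = frozenset({0, 1, 2, 4})
LABEL_NCR, LABEL_ED, LABEL_ET = 1, 2, 4
REGION_NAMES = ("WT", "TC", "ET")
#: labels included in each region channel, in (WT, TC, ET) order
REGION_LABELS = ((1, 2, 4), (1, 4), (4,))


def _validate_labels(voxels: np.ndarray):
    if voxels.ndim != 3:
        raise ValueError(f"label volume must have 3 spatial axes, got {voxels.ndim}")
    bad = np.setdiff1d(np.unique(voxels), sorted(VALID_LABELS))
    if bad.size:
        raise ValueError(f"unknown label value(s) {bad.tolist()}; expected subset of "
                         f"{sorted(VALID_LABELS)}")


@dataclass
class LabelVolume:
    """Integer voxel labels on a 3D grid, values in {0, 1, 2, 4}."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError(f"label voxels must be integer, got {self.voxels.dtype}")
        _validate_labels(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RegionMask:
    """Binary (3, D, H, W) masks in (WT, TC, ET) channel order."""

    channels: np.ndarray

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError(f"expected (3, D, H, W) channels, got {self.channels.shape}")
        vals = np.unique(self.channels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("region mask values must be 0/1")

    @property
    def wt(self) -> np.ndarray:
        return self.channels[0]

    @property
    def tc(self) -> np.ndarray:
        return self.channels[1]

    @property
    def et(self) -> np.ndarray:
        return self.channels[2]

    def is_nested(self) -> bool:
        """ET=1 ⇒ TC=1 ⇒ WT=1 at every voxel."""
        c = self.channels.astype(bool)
        return bool((~c[2] | c[1]).all() and (~c[1] | c[0]).all())


@dataclass
class MultiModalVolume:
    """Float (C, D, H, W) intensity grid; 4 modalities, or 5 with the
    foreground channel appended."""

    channels: np.ndarray
    modality_names: tuple[str, ...] = ("t1", "t1ce", "t2", "flair")
    spacing: tuple[float, float, float] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4:
            raise ValueError(f"expected (C, D, H, W) channels, got {self.channels.shape}")
        if not np.isfinite(self.channels).all():
            raise ValueError("intensity volume contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]


def labels_to_regions(labels: LabelVolume | np.ndarray) -> RegionMask:
    """Encode integer labels as the three overlapping region channels."""
    if isinstance(labels, LabelVolume):
        voxels = labels.voxels
    else:
        voxels = np.asarray(labels)
        _validate_labels(voxels)
    out = np.empty((3,) + voxels.shape, dtype=np.uint8)
    for i, members in enumerate(REGION_LABELS):
        out[i] = np.isin(voxels, members)
    return RegionMask(out)


def regions_nested(mask: RegionMask) -> bool:
    return mask.is_nested()


def foreground_channel(volume: MultiModalVolume | np.ndarray) -> np.ndarray:
    """Binary map of salient voxels: nonzero in *any* modality.

    Skull-stripped volumes have exactly-zero background, so this is a brain
    mask; it is appended as an extra input channel when the network is
    configured with 5 input channels.
    """
    channels = volume.channels if isinstance(volume, MultiModalVolume) else np.asarray(volume)
    if channels.ndim != 4 or channels.shape[0] < 1:
        raise ValueError("expected a (C, D, H, W) volume with at least one channel")
    return (channels != 0).any(axis=0).astype(np.uint8)


def append_foreground_channel(volume: MultiModalVolume) -> MultiModalVolume:
    fg = foreground_channel(volume)[None].astype(np.float32)
    return MultiModalVolume(
        channels=np.concatenate([volume.channels, fg], axis=0),
        modality_names=tuple(volume.modality_names) + ("foreground",),
        spacing=volume.spacing, affine=volume.affine,
    )


def _as_factors(factor) -> tuple[int, int, int]:
    if np.isscalar(factor):
        factor = (factor,) * 3
    f = tuple(int(v) for v in factor)
    if len(f) != 3 or any(v < 1 for v in f):
        raise ValueError(f"downsampling factors must be 3 positive integers, got {factor}")
    return f


def downsample_regions_nn(mask: RegionMask, factor) -> RegionMask:
    """Nearest-neighbor downsampling of a region mask.

    The sampling grid is anchored at index 0: output voxel ``i`` along an
    axis with factor ``f`` copies input voxel ``i*f``; the output extent is
    ``ceil(extent / f)``. Sampling is voxel-wise, so nesting is preserved.
    """
    fd, fh, fw = _as_factors(factor)
    return RegionMask(mask.channels[:, ::fd, ::fh, ::fw].copy())


def downsample_volume_nn(array: np.ndarray, factor) -> np.ndarray:
    """Nearest-neighbor downsampling of any (…, D, H, W) array (same grid)."""
    fd, fh, fw = _as_factors(factor)
    return np.ascontiguousarray(array[..., ::fd, ::fh, ::fw])
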