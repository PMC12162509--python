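"""Threshold cascade and enhancing-tumor component rules.

The three sigmoid region channels are mapped back to the integer label
vocabulary by a voxel-wise cascade of strict thresholds:

    WT < 0.45 → 0 (background)
    else TC < 0.40 → 2 (edema)
    else ET < 0.45 → 1 (NCR)
    else 4 (enhancing tumor)

Two ET clean-up rules then guard against spurious small enhancing-tumor
predictions (which are punishing under the empty-mask Dice convention):

1. per-component: every ET connected component with fewer than 16 voxels
   AND mean ET probability below 0.9 is relabeled NCR;
2. global: if the remaining ET voxels number fewer than 73 in total AND
   their mean ET probability is below 0.9, all ET becomes NCR.

Both rules only ever remove ET voxels, so the ET count is non-increasing
through post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .labels import LABEL_ET, LABEL_NCR, LabelVolume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class PostprocessConfig:
    thr_wt: float = 0.45
    thr_tc: float = 0.40
    thr_et: float = 0.45
    comp_min_size: int = 16
    comp_mean_thr: float = 0.9
    global_et_max: int = 73
    global_mean_thr: float = 0.9
    connectivity: int = 26
    enable_component_rules: bool = True

    def __post_init__(self):
        for name in ("thr_wt", "thr_tc", "thr_et"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.comp_min_size < 0 or self.global_et_max < 0:
            raise ValueError("component sizes must be >= 0")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")


def _as_probs(probs) -> np.ndarray:
    arr = np.asarray(getattr(probs, "channels", probs), dtype=np.float64)
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ValueError(f"expected (3, D, H, W) region probabilities, got {arr.shape}")
    if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    return arr


def regions_to_labels(probs, config: PostprocessConfig | None = None,
                      affine: np.ndarray | None = None) -> LabelVolume:
    """Voxel-wise threshold cascade from (WT, TC, ET) probabilities to labels."""
    config = config or PostprocessConfig()
    wt, tc, et = _as_probs(probs)
    labels = np.full(wt.shape, LABEL_ET, dtype=np.int16)
    labels[et < config.thr_et] = LABEL_NCR
    labels[tc < config.thr_tc] = 2
    labels[wt < config.thr_wt] = 0
    return LabelVolume(labels, affine=affine)


def filter_et_components(labels: LabelVolume, et_probs: np.ndarray,
                         config: PostprocessConfig | None = None) -> LabelVolume:
    """Relabel small, low-confidence ET connected components to NCR.

    A component is removed only when *both* conditions hold: size below
    ``comp_min_size`` and mean ET probability below ``comp_mean_thr``.
    """
    config = config or PostprocessConfig()
    et_probs = np.asarray(et_probs, dtype=np.float64)
    if et_probs.shape != labels.shape:
        raise ValueError(f"probability shape {et_probs.shape} != label shape {labels.shape}")
    et_mask = labels.voxels == LABEL_ET
    if not et_mask.any():
        return LabelVolume(labels.voxels.copy(), spacing=labels.spacing,
                           affine=labels.affine)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[config.connectivity])
    comp, n_comp = ndimage.label(et_mask, structure=structure)
    idx = np.arange(1, n_comp + 1)
    sizes = ndimage.sum_labels(et_mask, comp, idx)
    means = ndimage.mean(et_probs, comp, idx)
    drop = (sizes < config.comp_min_size) & (means < config.comp_mean_thr)
    out = labels.voxels.copy()
    if drop.any():
        out[np.isin(comp, idx[drop])] = LABEL_NCR
    return LabelVolume(out, spacing=labels.spacing, affine=labels.affine)


def global_et_replacement(labels: LabelVolume, et_probs: np.ndarray,
                          config: PostprocessConfig | None = None) -> LabelVolume:
    """Replace *all* ET by NCR when the total ET volume is small and uncertain.

    Triggers only when the ET voxel count is below ``global_et_max`` AND the
    mean ET probability over those voxels is below ``global_mean_thr``;
    vacuous when no ET voxel exists.
    """
    config = config or PostprocessConfig()
    et_probs = np.asarray(et_probs, dtype=np.float64)
    if et_probs.shape != labels.shape:
        raise ValueError(f"probability shape {et_probs.shape} != label shape {labels.shape}")
    out = labels.voxels.copy()
    et_mask = out == LABEL_ET
    count = int(et_mask.sum())
    if 0 < count < config.global_et_max and et_probs[et_mask].mean() < config.global_mean_thr:
        out[et_mask] = LABEL_NCR
    return LabelVolume(out, spacing=labels.spacing, affine=labels.affine)


def postprocess_probabilities(probs, config: PostprocessConfig | None = None,
                              affine: np.ndarray | None = None,
                              morphology_hook=None) -> LabelVolume:
    """Full pipeline: threshold cascade, then the two ET component stages.

    ``morphology_hook``, if given, is a callable LabelVolume -> LabelVolume
    applied last (e.g. user-supplied dilation/erosion); no morphological
    smoothing is performed by default.
    """
    config = config or PostprocessConfig()
    arr = _as_probs(probs)
    labels = regions_to_labels(arr, config, affine=affine)
    if config.enable_component_rules:
        labels = filter_et_components(labels, arr[2], config)
        labels = global_et_replacement(labels, arr[2], config)
    if morphology_hook is not None:
        labels = morphology_hook(labels)
    return labels
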