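"""Synthetic multi-modal phantom volumes with nested tumor regions.

Every stage of the pipeline (training, inference, post-processing,
evaluation) is exercisable on these phantoms without any external data.
A phantom case is a brain-shaped ellipsoid of nonzero intensity containing
three concentric tumor ellipsoids defining the nested regions
ET ⊆ TC ⊆ WT:

* label 4 (ET)  inside the innermost ellipsoid,
* label 1 (NCR) in the TC shell (middle minus inner),
* label 2 (ED)  in the WT shell (outer minus middle),
* label 0       elsewhere.

Each of the four "modalities" assigns every tissue a mean intensity and
adds i.i.d. Gaussian noise inside the brain mask; the per-tissue means are
chosen so the modalities carry partially redundant contrasts (edema bright
in the T2/FLAIR-like channels, enhancing tumor bright in the T1ce-like
channel), mimicking — not simulating — multi-modal MRI. Outside the brain
the intensity is exactly zero, so the salient-voxel channel is a brain
mask. Everything is a pure function of (seed, case_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import LabelVolume, MultiModalVolume

MODALITIES = ("t1", "t1ce", "t2", "flair")

#: per-tissue mean intensity in each modality (rows: tissue, cols: modality)
DEFAULT_INTENSITY_MEANS: dict[str, tuple[float, float, float, float]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (0.50, 0.50, 0.50, 0.50),
    "ncr": (0.30, 0.35, 0.65, 0.60),
    "ed": (0.45, 0.45, 0.75, 0.85),
    "et": (0.75, 0.95, 0.55, 0.65),
}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    n_cases: int = 10
    radii: tuple[float, float, float] = (14.0, 9.0, 5.0)   # (r_wt, r_tc, r_et)
    radius_jitter: float = 1.0
    center_jitter: float = 3.0
    brain_fraction: float = 0.42       # brain ellipsoid semi-axis / extent
    intensity_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS))
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        r_wt, r_tc, r_et = self.radii
        # strict nesting is the normal case; degenerate (zero) inner radii are
        # allowed so shells can be tested in isolation
        if not (r_wt > 0 and r_wt >= r_tc >= r_et >= 0):
            raise ValueError(f"radii must satisfy r_wt >= r_tc >= r_et >= 0 with "
                             f"r_wt > 0, got {self.radii}")
        if r_wt + self.radius_jitter + self.center_jitter >= min(self.shape) / 2:
            raise ValueError("tumor (radius + jitter) does not fit inside the volume")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / max(r, 1e-9)) ** 2
    return acc <= 1.0


def _case_rng(config: PhantomConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, int(case_index)])


def generate_case(config: PhantomConfig, case_index: int
                  ) -> tuple[MultiModalVolume, LabelVolume]:
    """Deterministically generate one phantom case."""
    rng = _case_rng(config, case_index)
    shape = tuple(config.shape)
    center = np.array(shape) / 2.0 - 0.5
    brain = _ellipsoid(shape, center, [config.brain_fraction * s for s in shape])

    tumor_center = center + rng.uniform(-config.center_jitter, config.center_jitter, 3)
    radii = np.array(config.radii) + rng.uniform(-config.radius_jitter,
                                                 config.radius_jitter, 3)
    radii = np.maximum.accumulate(radii[::-1])[::-1]  # keep r_wt >= r_tc >= r_et
    r_wt, r_tc, r_et = radii
    wt = _ellipsoid(shape, tumor_center, (r_wt,) * 3) & brain
    tc = _ellipsoid(shape, tumor_center, (r_tc,) * 3) & wt if r_tc > 0 else np.zeros_like(wt)
    et = _ellipsoid(shape, tumor_center, (r_et,) * 3) & tc if r_et > 0 else np.zeros_like(wt)

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = 2          # ED in the outer shell
    labels[tc] = 1          # NCR in the core shell
    labels[et] = 4          # enhancing tumor innermost

    means = config.intensity_means
    tissue_masks = {
        "brain": brain & (labels == 0),
        "ncr": labels == 1, "ed": labels == 2, "et": labels == 4,
    }
    channels = np.zeros((len(MODALITIES),) + shape, dtype=np.float32)
    for m, _name in enumerate(MODALITIES):
        canvas = np.zeros(shape, dtype=np.float32)
        for tissue, mask in tissue_masks.items():
            canvas[mask] = means[tissue][m]
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, shape).astype(np.float32)
            canvas[brain] += noise[brain]
        channels[m] = canvas

    affine = np.eye(4)
    return (MultiModalVolume(channels, modality_names=MODALITIES, affine=affine),
            LabelVolume(labels, affine=affine))


def generate_cases(config: PhantomConfig) -> list[tuple[MultiModalVolume, LabelVolume]]:
    return [generate_case(config, i) for i in range(config.n_cases)]


def generate_dataset(config: PhantomConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write ``n_cases`` phantoms as NIfTI files plus a regeneration manifest.

    Layout: ``<out_dir>/case_<i>/<modality>.nii.gz`` and ``seg.nii.gz``;
    the manifest CSV records (case_id, seed, case_index, shape, radii).
    """
    from . import io as gio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(config.n_cases):
        volume, labels = generate_case(config, i)
        case_id = f"case_{i:03d}"
        case_dir = out_dir / case_id
        case_dir.mkdir(exist_ok=True)
        for m, name in enumerate(MODALITIES):
            gio.write_nifti(case_dir / f"{name}.nii.gz", volume.channels[m],
                            affine=volume.affine)
        gio.write_nifti(case_dir / "seg.nii.gz", labels.voxels, affine=labels.affine)
        rows.append({"case_id": case_id, "seed": config.seed, "case_index": i,
                     "shape": "x".join(map(str, config.shape)),
                     "r_wt": config.radii[0], "r_tc": config.radii[1],
                     "r_et": config.radii[2], "noise_sd": config.noise_sd})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def threshold_oracle_wt(volume: MultiModalVolume, config: PhantomConfig) -> np.ndarray:
    """Intensity-threshold segmentation of WT (sanity floor for learnability).

    Classifies a voxel as whole tumor when its FLAIR-like channel exceeds
    the midpoint between the brain and edema means; used only as an
    independent check that noise-free phantoms are trivially segmentable.
    """
    flair = volume.channels[MODALITIES.index("flair")]
    lo = config.intensity_means["brain"][3]
    hi = min(config.intensity_means[t][3] for t in ("ed", "ncr", "et"))
    return (flair > 0.5 * (lo + hi)).astype(np.uint8)
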