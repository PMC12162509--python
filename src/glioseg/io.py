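"""NIfTI reading/writing, case records, configs, and checkpoints."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .labels import VALID_LABELS, LabelVolume, MultiModalVolume
from .phantom import MODALITIES

AFFINE_TOL = 1e-4


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path}")
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), np.asarray(img.affine)


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None):
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)  # preserve an integer dtype on disk
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.eye(4) if affine is None else affine), str(path))


def read_label_volume(path) -> LabelVolume:
    data, affine = read_nifti(path)
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise ValueError(f"{path}: label volume is not integer-valued")
        arr = rounded.astype(np.int16)
    bad = np.setdiff1d(np.unique(arr), sorted(VALID_LABELS))
    if bad.size:
        raise ValueError(f"{path}: illegal label value(s) {bad.tolist()}")
    return LabelVolume(arr.astype(np.int16), affine=affine)


def write_label_volume(path, labels: LabelVolume):
    write_nifti(path, labels.voxels, affine=labels.affine)


def write_probabilities(path, probs: np.ndarray, affine: np.ndarray | None = None):
    """Write a (3, D, H, W) probability map as a 4D NIfTI (channels last)."""
    probs = np.asarray(probs, dtype=np.float32)
    write_nifti(path, np.moveaxis(probs, 0, -1), affine=affine)


def read_probabilities(path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_nifti(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (D, H, W, 3) probability volume, "
                         f"got {data.shape}")
    return np.moveaxis(np.asarray(data, dtype=np.float32), -1, 0), affine


@dataclass
class CaseRecord:
    case_id: str
    modality_paths: tuple[Path, ...]
    label_path: Path | None = None
    fold: int | None = None


def read_case(record: CaseRecord) -> tuple[MultiModalVolume, LabelVolume | None]:
    """Load a case's modalities (stacked in declared order) and labels.

    All files must exist and agree on spatial shape and affine (within
    1e-4 on affine entries). A 4-channel single file is also accepted as
    the sole modality path.
    """
    arrays, affines = [], []
    for p in record.modality_paths:
        data, affine = read_nifti(p)
        if data.ndim == 4:
            for c in range(data.shape[-1]):
                arrays.append(np.asarray(data[..., c], dtype=np.float32))
                affines.append(affine)
        else:
            arrays.append(np.asarray(data, dtype=np.float32))
            affines.append(affine)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"{record.case_id}: modality shapes differ: {shapes}")
    for p, affine in zip(record.modality_paths, affines):
        if np.abs(affine - affines[0]).max() > AFFINE_TOL:
            raise ValueError(f"{record.case_id}: affine of {p} deviates beyond "
                             f"{AFFINE_TOL}")
    names = MODALITIES if len(arrays) == 4 else tuple(
        f"ch{i}" for i in range(len(arrays)))
    volume = MultiModalVolume(np.stack(arrays), modality_names=names,
                              affine=affines[0])
    labels = None
    if record.label_path is not None:
        labels = read_label_volume(record.label_path)
        if labels.shape != volume.spatial_shape:
            raise ValueError(f"{record.case_id}: label shape {labels.shape} != "
                             f"volume shape {volume.spatial_shape}")
        if np.abs(labels.affine - affines[0]).max() > AFFINE_TOL:
            raise ValueError(f"{record.case_id}: label affine deviates beyond "
                             f"{AFFINE_TOL}")
    return volume, labels


def discover_cases(data_dir) -> list[CaseRecord]:
    """Find ``case_*/`` directories with per-modality files and optional seg."""
    data_dir = Path(data_dir)
    records = []
    for case_dir in sorted(data_dir.glob("case_*")):
        if not case_dir.is_dir():
            continue
        paths = tuple(case_dir / f"{m}.nii.gz" for m in MODALITIES)
        seg = case_dir / "seg.nii.gz"
        records.append(CaseRecord(case_id=case_dir.name, modality_paths=paths,
                                  label_path=seg if seg.exists() else None))
    if not records:
        raise FileNotFoundError(f"no case_* directories under {data_dir}")
    return records


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_checkpoint(path, checkpoint: dict):
    """Single-file checkpoint: parameter arrays + JSON-embedded configs."""
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    arrays = {f"param:{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param:"):]: data[k] for k in data.files
                 if k.startswith("param:")}
    meta["state"] = state
    return meta
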