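"""Patch sampling, optimization schedule, early stopping, cross-validation.

Training follows the standard recipe for this architecture family: Adam (lr 1e-4, weight decay 1e-5),
batch size 2, 128³ patches (scalable down), ReduceLROnPlateau on the
validation loss, early stopping with patience 10, and k-fold
cross-validation (default k = 5). Patches are sampled with a configurable
foreground bias — with probability ``fg_bias`` the patch center is drawn
from tumor voxels — because uniform sampling on sparse tumors starves the
region losses. The per-epoch history records each supervision head's loss
(columns L1, L2, L3) and the total.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd

from .labels import (LabelVolume, MultiModalVolume, append_foreground_channel,
                     labels_to_regions)
from .losses import LossConfig, combined_loss, deep_supervision_loss, vae_loss
from .networks import NetworkConfig, build_network
from .nn import Adam, EarlyStopper, ReduceLROnPlateau, no_grad


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 2
    patch_size: tuple[int, int, int] = (128, 128, 128)
    max_epochs: int = 100
    patience: int = 10
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    folds: int = 5
    holdout_fraction: float = 0.2
    seed: int = 0
    fg_bias: float = 0.5
    patches_per_case: int = 2       # sampled patches per training case per epoch

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer rates")
        if not 0.0 <= self.fg_bias <= 1.0:
            raise ValueError("fg_bias must lie in [0, 1]")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patches_per_case < 1:
            raise ValueError("batch_size, max_epochs and patches_per_case must be >= 1")
        self.patch_size = tuple(int(v) for v in (
            (self.patch_size,) * 3 if np.isscalar(self.patch_size) else self.patch_size))


@dataclass
class FoldSplit:
    fold_id: int
    train_case_ids: list
    val_case_ids: list


def make_folds(case_ids, k: int, seed: int) -> list[FoldSplit]:
    """Deterministic k-fold split; validation sizes differ by at most 1."""
    case_ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(case_ids):
        raise ValueError(f"k = {k} exceeds the number of cases ({len(case_ids)})")
    perm = np.random.default_rng(seed).permutation(len(case_ids))
    chunks = np.array_split(perm, k)
    folds = []
    for fold_id, chunk in enumerate(chunks):
        val = [case_ids[i] for i in chunk]
        train = [case_ids[i] for i in perm if case_ids[i] not in set(val)]
        folds.append(FoldSplit(fold_id, train, val))
    return folds


def _pad_to_patch(channels: np.ndarray, voxels: np.ndarray, patch):
    spatial = channels.shape[1:]
    spec = []
    for extent, p in zip(spatial, patch):
        deficit = max(p - extent, 0)
        spec.append((deficit // 2, deficit - deficit // 2))
    if any(b or a for b, a in spec):
        channels = np.pad(channels, ((0, 0),) + tuple(spec))
        voxels = np.pad(voxels, tuple(spec))
    return channels, voxels


def sample_patch(volume: MultiModalVolume, labels: LabelVolume, config: TrainConfig,
                 rng: np.random.Generator, center: tuple[int, int, int] | None = None):
    """Draw one co-registered (input, region-target) patch pair.

    With probability ``fg_bias`` the patch center is a uniformly drawn
    tumor voxel (the origin is clipped to keep the window in bounds);
    otherwise the origin is uniform. An explicit ``center`` overrides the
    random draw. Volumes smaller than the patch are zero-padded.
    """
    patch = config.patch_size
    channels, voxels = _pad_to_patch(volume.channels, labels.voxels, patch)
    spatial = channels.shape[1:]
    max_origin = [e - p for e, p in zip(spatial, patch)]

    if center is None:
        use_fg = rng.random() < config.fg_bias
        fg = np.argwhere(voxels > 0)
        if use_fg and fg.size == 0:
            if config.fg_bias >= 1.0:
                warnings.warn("fg_bias = 1 but the volume has no tumor voxels; "
                              "falling back to uniform patch sampling")
            use_fg = False
        if use_fg:
            center = fg[rng.integers(len(fg))]
        else:
            origin = [int(rng.integers(m + 1)) for m in max_origin]
    if center is not None:
        origin = [int(np.clip(c - p // 2, 0, m))
                  for c, p, m in zip(center, patch, max_origin)]

    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
    x = channels[(slice(None),) + sl]
    y = labels_to_regions(LabelVolume(np.ascontiguousarray(voxels[sl]))).channels
    return np.ascontiguousarray(x), y


def _validation_patch(volume, labels, config: TrainConfig):
    """Deterministic patch centered on the tumor centroid (or the volume)."""
    fg = np.argwhere(labels.voxels > 0)
    if len(fg):
        center = tuple(int(round(c)) for c in fg.mean(axis=0))
    else:
        center = tuple(s // 2 for s in labels.shape)
    return sample_patch(volume, labels, config, np.random.default_rng(0), center=center)


class NonFiniteLossError(RuntimeError):
    """Raised when the training loss becomes NaN/inf; carries a snapshot."""

    def __init__(self, message: str, snapshot: dict):
        super().__init__(message)
        self.snapshot = snapshot


def train_model(dataset, net_config: NetworkConfig, loss_config: LossConfig,
                train_config: TrainConfig, val_indices=None):
    """Train a network on (volume, labels) pairs; return (checkpoint, history).

    ``dataset`` is a list of (MultiModalVolume, LabelVolume) tuples. The
    validation set is ``val_indices`` if given, else a ``holdout_fraction``
    split drawn from the training seed. The best-validation parameters are
    kept and returned in the checkpoint.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    min_axis = 2 ** (net_config.depth - 1)
    if any(p < min_axis for p in train_config.patch_size):
        raise ValueError(f"patch_size {train_config.patch_size} must be >= "
                         f"2^(depth-1) = {min_axis} on every axis")

    rng = np.random.default_rng([int(train_config.seed) % 2**31, 17])
    n = len(dataset)
    if val_indices is None:
        n_val = max(1, int(round(train_config.holdout_fraction * n)))
        if n_val >= n:
            raise ValueError("holdout split leaves no training cases")
        perm = rng.permutation(n)
        val_indices = sorted(int(i) for i in perm[:n_val])
    val_indices = list(val_indices)
    train_indices = [i for i in range(n) if i not in set(val_indices)]

    def prepare(case):
        volume, labels = case
        if net_config.in_channels == volume.channels.shape[0] + 1:
            volume = append_foreground_channel(volume)
        return volume, labels

    train_cases = [prepare(dataset[i]) for i in train_indices]
    val_patches = [_validation_patch(v, l, train_config)
                   for v, l in (prepare(dataset[i]) for i in val_indices)]

    net = build_network(net_config, np.random.default_rng(
        [int(train_config.seed) % 2**31, 29]))
    params = net.parameters()
    optimizer = Adam(params, lr=train_config.learning_rate,
                     weight_decay=train_config.weight_decay)
    scheduler = ReduceLROnPlateau(optimizer, factor=train_config.scheduler_factor,
                                  patience=train_config.scheduler_patience,
                                  min_lr=train_config.min_lr)
    stopper = EarlyStopper(patience=train_config.patience)
    is_vae = net_config.variant == "ae_unet"
    vae_rng = np.random.default_rng([int(train_config.seed) % 2**31, 43])

    history_rows = []
    best_state = net.state_dict()
    best_val = np.inf
    n_heads = net_config.n_heads

    def epoch_loss(x_batch, y_batch, train_mode: bool):
        out = net.forward(x_batch, rng=vae_rng if (is_vae and train_mode) else None)
        if n_heads > 1:
            total, per_head = deep_supervision_loss(out.probs, y_batch, loss_config,
                                                    return_per_head=True)
        else:
            total = combined_loss(out.probs[0], y_batch, loss_config)
            per_head = [total]
        if is_vae:
            total = total + vae_loss(out.reconstruction, x_batch, out.mu,
                                     out.log_var, loss_config)
        return total, per_head

    for epoch in range(train_config.max_epochs):
        order = np.concatenate([rng.permutation(len(train_cases))
                                for _ in range(train_config.patches_per_case)])
        head_sums = np.zeros(n_heads)
        total_sum, n_batches = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            batch_idx = order[start:start + train_config.batch_size]
            xs, ys = zip(*(sample_patch(*train_cases[i], train_config, rng)
                           for i in batch_idx))
            x_batch = np.stack(xs).astype(np.float32)
            y_batch = np.stack(ys).astype(np.float32)
            total, per_head = epoch_loss(x_batch, y_batch, train_mode=True)
            value = float(total)
            if not np.isfinite(value):
                raise NonFiniteLossError(
                    f"non-finite training loss at epoch {epoch}",
                    snapshot={"epoch": epoch, "batch_cases": batch_idx.tolist(),
                              "loss": value, "lr": optimizer.lr})
            net.zero_grad()
            total.backward()
            optimizer.step()
            head_sums += [float(h) for h in per_head]
            total_sum += value
            n_batches += 1

        with no_grad():
            val_losses = []
            for x_val, y_val in val_patches:
                v_total, _ = epoch_loss(x_val[None].astype(np.float32),
                                        y_val[None].astype(np.float32),
                                        train_mode=False)
                val_losses.append(float(v_total))
            val_loss = float(np.mean(val_losses))

        row = {"epoch": epoch, "total": total_sum / n_batches,
               "val_loss": val_loss, "lr": optimizer.lr}
        for a in range(3):
            row[f"L{a + 1}"] = head_sums[a] / n_batches if a < n_heads else np.nan
        history_rows.append(row)

        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
        scheduler.step(val_loss)
        if stopper.update(val_loss):
            break

    net.load_state_dict(best_state)
    history = pd.DataFrame(history_rows,
                           columns=["epoch", "L1", "L2", "L3", "total", "val_loss", "lr"])
    checkpoint = {
        "state": best_state,
        "net_config": asdict(net_config),
        "loss_config": asdict(loss_config),
        "train_config": asdict(train_config),
        "best_val_loss": float(best_val),
        "epochs_run": len(history_rows),
        "val_indices": val_indices,
    }
    return checkpoint, history


def grid_search(dataset, net_config: NetworkConfig, loss_config: LossConfig,
                train_config: TrainConfig, grid: dict[str, list]) -> pd.DataFrame:
    """Exhaustive sweep over training/loss settings; one row per combination.

    ``grid`` maps parameter names (fields of TrainConfig or LossConfig,
    e.g. ``learning_rate``, ``weight_decay``, ``alpha``) to candidate
    values. Each combination is trained from scratch and scored by its
    best validation loss. A convenience utility only — it implements no
    particular search protocol or budget.
    """
    from dataclasses import replace
    from itertools import product as iproduct

    names = list(grid)
    rows = []
    train_fields = {f.name for f in fields(TrainConfig)}
    loss_fields = {f.name for f in fields(LossConfig)}
    for combo in iproduct(*(grid[n] for n in names)):
        assignment = dict(zip(names, combo))
        tr = replace(train_config, **{k: v for k, v in assignment.items()
                                      if k in train_fields})
        lo = replace(loss_config, **{k: v for k, v in assignment.items()
                                     if k in loss_fields})
        unknown = set(assignment) - train_fields - loss_fields
        if unknown:
            raise ValueError(f"unknown sweep parameter(s): {sorted(unknown)}")
        checkpoint, _ = train_model(dataset, net_config, lo, tr)
        rows.append({**assignment, "best_val_loss": checkpoint["best_val_loss"],
                     "epochs_run": checkpoint["epochs_run"]})
    return pd.DataFrame(rows).sort_values("best_val_loss").reset_index(drop=True)


def rebuild_network(checkpoint: dict):
    """Reconstruct the network graph from an embedded checkpoint config."""
    net_config = NetworkConfig(**checkpoint["net_config"])
    net = build_network(net_config, np.random.default_rng(0))
    net.load_state_dict(checkpoint["state"])
    return net
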