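"""Training and prediction for the multi-output U-net.

The loss is a weighted sum of binary cross-entropy (on logits, for
segmentation) and mean squared errors (for the longitude and diameter
maps), every term averaged over all voxels — regression targets are the
embedded volumes, zero outside the bowel mask.  By default each regression
weight is 1 / mean(target^2) over the training set, so every weighted term
starts near 1 (the loss of an all-zero prediction) and the three terms sit
within one order of magnitude of each other, ensuring all are optimized;
fixed weights can be given instead.

Prediction thresholds the segmentation at probability 0.5 and applies the
resulting mask to the diameter and longitude outputs, whose support would
otherwise differ from the segmentation's; diameters are converted from
voxel units back to mm using the mean in-plane voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..embed import LabelVolumes
from ..grid import VolumeGrid
from ..preprocess import diameter_mm_to_voxel, diameter_voxel_to_mm
from .engine import Adam
from .unet import UNet3D, UNetConfig, build_unet

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingSample",
    "make_training_sample",
    "multitask_loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: Characteristic scales used to balance the loss terms: the longitude
#: coordinate tops out at 150 and 30 mm is the clinically salient diameter.
LONGITUDE_SCALE = 150.0
DIAMETER_SCALE_MM = 30.0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, learning rate 1e-3).

    ``w_long``/``w_diam`` of None auto-balance against the training targets
    (1 / mean squared target value); explicit numbers override.
    """

    lr: float = 1e-3
    epochs: int = 222
    lr_final_fraction: float = 1.0  # 1.0: constant lr; < 1: cosine decay
    w_seg: float = 1.0
    w_long: float | None = None
    w_diam: float | None = None
    val_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.val_fraction < 0.5):
            raise ValueError(f"val_fraction must be in [0, 0.5), got {self.val_fraction}")
        for w in (self.w_seg, self.w_long, self.w_diam):
            if w is not None and w <= 0:
                raise ValueError("loss weights must be positive")


@dataclass
class TrainingSample:
    """A preprocessed (normalized CT, target triple) pair.

    ``diameter`` is in voxel units, per the convention of scaling diameters
    by the voxel dimensions before training.
    """

    ct: np.ndarray  # window/leveled, in [0, 1]
    segmentation: np.ndarray
    longitude: np.ndarray
    diameter: np.ndarray  # voxel units
    grid: VolumeGrid


def make_training_sample(ct_norm: np.ndarray, truth: LabelVolumes) -> TrainingSample:
    """Package normalized CT and label volumes, scaling diameter to voxels."""
    return TrainingSample(
        ct=np.asarray(ct_norm, dtype=np.float32),
        segmentation=np.asarray(truth.segmentation, dtype=np.float32),
        longitude=np.asarray(truth.longitude, dtype=np.float32),
        diameter=np.asarray(
            diameter_mm_to_voxel(truth.diameter, truth.grid), dtype=np.float32
        ),
        grid=truth.grid,
    )


def multitask_loss(
    outputs: dict[str, np.ndarray],
    sample: TrainingSample,
    weights: tuple[float, float, float],
) -> tuple[float, dict[str, float], dict[str, np.ndarray]]:
    """Weighted BCE + MSE losses and their gradients w.r.t. the raw outputs.

    Returns (total, per-term weighted breakdown, per-head gradient volumes).
    BCE is computed on logits in the numerically stable formulation.
    """
    w_seg, w_long, w_diam = weights
    z = outputs["segmentation"].astype(np.float64)
    y = sample.segmentation
    if z.shape != y.shape:
        raise ValueError(f"prediction shape {z.shape} != target shape {y.shape}")
    n = z.size
    bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    d_seg = (w_seg * (p - y) / n).astype(np.float32)

    def mse(pred, target, w):
        r = pred.astype(np.float64) - target
        return float(np.mean(r * r)), (w * 2.0 * r / n).astype(np.float32)

    mse_long, d_long = mse(outputs["longitude"], sample.longitude, w_long)
    mse_diam, d_diam = mse(outputs["diameter"], sample.diameter, w_diam)

    breakdown = {
        "seg": w_seg * bce,
        "long": w_long * mse_long,
        "diam": w_diam * mse_diam,
    }
    total = sum(breakdown.values())
    grads = {"segmentation": d_seg, "longitude": d_long, "diameter": d_diam}
    return total, breakdown, grads


def resolve_weights(
    config: TrainConfig, dataset: list[TrainingSample]
) -> tuple[float, float, float]:
    """Concrete (w_seg, w_long, w_diam) for a training set.

    Auto-balanced weights are 1 / mean(target^2) over all voxels of the
    training samples, putting each regression term on the order of the
    initial cross-entropy; characteristic-scale constants (150 for
    longitude, 30 mm in voxel units for diameter) are the fallback when the
    targets are degenerate (empty masks).
    """

    def _auto(fields: list[np.ndarray], fallback_scale: float) -> float:
        ms = float(np.mean([np.mean(np.square(f, dtype=np.float64)) for f in fields]))
        return 1.0 / ms if ms > 0 else 1.0 / fallback_scale**2

    grid = dataset[0].grid
    w_long = config.w_long
    if w_long is None:
        w_long = _auto([s.longitude for s in dataset], LONGITUDE_SCALE)
    w_diam = config.w_diam
    if w_diam is None:
        scale_vox = DIAMETER_SCALE_MM / ((grid.spacing[0] + grid.spacing[1]) / 2.0)
        w_diam = _auto([s.diameter for s in dataset], scale_vox)
    return config.w_seg, w_long, w_diam


@dataclass
class TrainResult:
    """A trained model plus its per-epoch loss history."""

    model: UNet3D
    history: pd.DataFrame
    weights: tuple[float, float, float]

    def summary(self) -> str:
        first, last = self.history.iloc[0], self.history.iloc[-1]
        lines = [
            "U-net training summary",
            "----------------------",
            f"epochs:            {len(self.history)}",
            f"loss weights:      seg={self.weights[0]:.3g} long={self.weights[1]:.3g} diam={self.weights[2]:.3g}",
            f"train loss:        {first.train_total:.4f} -> {last.train_total:.4f}",
            f"  segmentation:    {first.train_seg:.4f} -> {last.train_seg:.4f}",
            f"  longitude:       {first.train_long:.4f} -> {last.train_long:.4f}",
            f"  diameter:        {first.train_diam:.4f} -> {last.train_diam:.4f}",
        ]
        if "val_total" in self.history and not np.isnan(last.val_total):
            lines.append(f"validation loss:   {first.val_total:.4f} -> {last.val_total:.4f}")
        return "\n".join(lines)


def train(
    model: UNet3D,
    dataset: list[TrainingSample],
    config: TrainConfig,
) -> TrainResult:
    """Optimize the model on (CT, label) pairs; deterministic given seed.

    A fraction of the dataset (``val_fraction``, 5% by default, at least
    one sample when the fraction is positive) is held out for monitoring
    and never trained on.  Batch size is 1.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * len(dataset)))
    if config.val_fraction > 0 and n_val == 0 and len(dataset) > 1:
        n_val = 1
    order = rng.permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]

    weights = resolve_weights(config, train_set)
    opt = Adam(model.params(), lr=config.lr)
    rows = []
    for epoch in range(config.epochs):
        if config.lr_final_fraction < 1.0 and config.epochs > 1:
            lo = config.lr * config.lr_final_fraction
            frac = 0.5 * (1.0 + np.cos(np.pi * epoch / (config.epochs - 1)))
            opt.lr = lo + (config.lr - lo) * frac
        perm = rng.permutation(len(train_set))
        terms = {"total": [], "seg": [], "long": [], "diam": []}
        for i in perm:
            s = train_set[i]
            opt.zero_grad()
            out = model.forward(s.ct, train=True)
            total, breakdown, grads = multitask_loss(out, s, weights)
            model.backward(grads)
            opt.step()
            terms["total"].append(total)
            for k in ("seg", "long", "diam"):
                terms[k].append(breakdown[k])
        row = {"epoch": epoch, **{f"train_{k}": float(np.mean(v)) for k, v in terms.items()}}
        if val_set:
            vterms = {"total": [], "seg": [], "long": [], "diam": []}
            for s in val_set:
                out = model.forward(s.ct, train=False)
                total, breakdown, _ = multitask_loss(out, s, weights)
                vterms["total"].append(total)
                for k in ("seg", "long", "diam"):
                    vterms[k].append(breakdown[k])
            row.update({f"val_{k}": float(np.mean(v)) for k, v in vterms.items()})
        rows.append(row)
    return TrainResult(model, pd.DataFrame(rows), weights)


def predict(model: UNet3D, ct_norm: np.ndarray, grid: VolumeGrid) -> LabelVolumes:
    """Predict masked label volumes from a normalized CT.

    The binary mask is the thresholded sigmoid output; diameter and
    longitude are zeroed outside it (their support may otherwise differ)
    and clamped inside it to their physical ranges (diameter positive,
    longitude within the 10-150 coordinate), then diameter is rescaled from
    voxel units to mm.
    """
    if tuple(ct_norm.shape) != tuple(grid.shape):
        raise ValueError(f"ct shape {ct_norm.shape} != grid shape {grid.shape}")
    out = model.forward(np.asarray(ct_norm, dtype=np.float32), train=False)
    mask = out["segmentation"] >= 0.0  # logit >= 0 <=> probability >= 0.5
    diam_mm = diameter_voxel_to_mm(out["diameter"].astype(float), grid)
    lon = out["longitude"].astype(float)
    diam_mm = np.where(mask, np.maximum(diam_mm, 1e-6), 0.0)
    lon = np.where(mask, np.clip(lon, 10.0, 150.0), 0.0)
    return LabelVolumes(mask.astype(np.uint8), diam_mm, lon, grid)


def save_checkpoint(path, model: UNet3D) -> None:
    """Write weights, running stats and the architecture config to one file."""
    cfg = model.config
    meta = np.array(
        [
            cfg.base_channels,
            cfg.depth,
            cfg.max_channels,
            cfg.convs_per_level,
            cfg.kernel,
            int(cfg.bottleneck_skip),
            cfg.seed,
        ],
        dtype=np.int64,
    )
    np.savez_compressed(
        path, __meta=meta, __dropout=np.float64(cfg.dropout), **model.state_arrays()
    )


def load_checkpoint(path) -> UNet3D:
    with np.load(path) as data:
        meta = data["__meta"]
        cfg = UNetConfig(
            base_channels=int(meta[0]),
            depth=int(meta[1]),
            max_channels=int(meta[2]),
            convs_per_level=int(meta[3]),
            kernel=int(meta[4]),
            dropout=float(data["__dropout"]),
            bottleneck_skip=bool(meta[5]),
            seed=int(meta[6]),
        )
        model = build_unet(cfg)
        model.load_state_arrays({k: data[k] for k in data.files})
    return model
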