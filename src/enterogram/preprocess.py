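"""CT/label normalization, padding, resizing and augmentation.

The fixed composition order for inference is pad -> resize -> window/level;
train-time augmentation acts on the padded native-resolution volumes before
resizing.  CT intensities are window/leveled with 400/40 HU, padding uses
-1000 HU (air) for the CT and 0 for labels, and augmentation applies one
rigid + isotropic-scale transform (|rotation| <= 15 deg, |translation| <=
15 mm, scale within 15% of unity) identically to the CT (trilinear, air
fill) and to the three label volumes (nearest-neighbor, zero fill).

Diameter maps keep mm units through these operations; conversion to voxel
units for training, and back after prediction, is an explicit separate step
using the mean in-plane voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "AugmentParams",
    "window_level",
    "pad_axial",
    "resize",
    "augment",
    "diameter_mm_to_voxel",
    "diameter_voxel_to_mm",
]

DEFAULT_WINDOW = 400.0
DEFAULT_LEVEL = 40.0
PAD_HU = -1000.0
PAD_QUANTUM = 192

MAX_ROT_DEG = 15.0
MAX_TRANS_MM = 15.0
MAX_SCALE_DEV = 0.15


def window_level(
    hu: np.ndarray, window: float = DEFAULT_WINDOW, level: float = DEFAULT_LEVEL
) -> np.ndarray:
    """Map HU to [0, 1] with a display window: level-w/2 -> 0, level+w/2 -> 1."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    return np.clip((np.asarray(hu, dtype=float) - (level - window / 2.0)) / window, 0.0, 1.0)


def pad_axial(
    field: np.ndarray,
    quantum: int = PAD_QUANTUM,
    pad_value: float = PAD_HU,
) -> np.ndarray:
    """Pad the axial (last) axis up to the next multiple of *quantum*.

    Padding is appended at the superior end only, so the origin of the grid
    is unchanged.  Use ``pad_value=0`` for label volumes.
    """
    if quantum < 1:
        raise ValueError(f"quantum must be >= 1, got {quantum}")
    nz = field.shape[-1]
    target = int(np.ceil(nz / quantum)) * quantum
    if target == nz:
        return field.copy()
    width = [(0, 0)] * (field.ndim - 1) + [(0, target - nz)]
    return np.pad(field, width, mode="constant", constant_values=pad_value)


def resize(
    field: np.ndarray,
    target_shape: tuple[int, int, int],
    mode: str,
    grid: VolumeGrid | None = None,
) -> tuple[np.ndarray, VolumeGrid | None]:
    """Resample to *target_shape*, preserving the world extent.

    ``mode='continuous'`` uses trilinear interpolation (CT); ``mode='label'``
    uses nearest-neighbor (segmentation/diameter/longitude).  New voxel
    centers are aligned so the sampled world extent is preserved, and the
    returned grid carries the rescaled spacing.
    """
    if mode not in ("continuous", "label"):
        raise ValueError(f"mode must be 'continuous' or 'label', got {mode!r}")
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    old_shape = np.asarray(field.shape)
    new_shape = np.asarray(target_shape)
    if tuple(old_shape) == target_shape:
        out = field.copy()
    else:
        ratio = old_shape / new_shape
        coords = [
            (np.arange(n) + 0.5) * r - 0.5 for n, r in zip(new_shape, ratio)
        ]
        mesh = np.meshgrid(*coords, indexing="ij")
        order = 1 if mode == "continuous" else 0
        out = ndimage.map_coordinates(
            np.asarray(field, dtype=float),
            np.stack(mesh),
            order=order,
            mode="nearest",
        )
        if mode == "label" and np.issubdtype(field.dtype, np.integer):
            out = out.astype(field.dtype)
    new_grid = None
    if grid is not None:
        spacing = np.asarray(grid.spacing) * old_shape / new_shape
        origin = np.asarray(grid.origin) + 0.5 * (spacing - np.asarray(grid.spacing))
        new_grid = VolumeGrid(target_shape, tuple(spacing), tuple(origin))
    return out, new_grid


@dataclass(frozen=True)
class AugmentParams:
    """One rigid + isotropic-scale augmentation transform.

    Rotation in degrees per axis, translation in mm per axis, one isotropic
    scale factor.  Identity is (0, 0, 0), (0, 0, 0), 1.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if any(abs(r) > MAX_ROT_DEG for r in self.rotation_deg):
            raise ValueError(f"|rotation| must be <= {MAX_ROT_DEG} deg: {self.rotation_deg}")
        if any(abs(t) > MAX_TRANS_MM for t in self.translation_mm):
            raise ValueError(f"|translation| must be <= {MAX_TRANS_MM} mm: {self.translation_mm}")
        if abs(self.scale - 1.0) > MAX_SCALE_DEV:
            raise ValueError(f"scale must be within 15% of 1: {self.scale}")

    @property
    def is_identity(self) -> bool:
        return (
            all(r == 0 for r in self.rotation_deg)
            and all(t == 0 for t in self.translation_mm)
            and self.scale == 1.0
        )

    @classmethod
    def random(cls, seed: int) -> "AugmentParams":
        rng = np.random.default_rng(seed)
        return cls(
            tuple(rng.uniform(-MAX_ROT_DEG, MAX_ROT_DEG, 3)),
            tuple(rng.uniform(-MAX_TRANS_MM, MAX_TRANS_MM, 3)),
            float(rng.uniform(1 - MAX_SCALE_DEV, 1 + MAX_SCALE_DEV)),
        )

    def matrix(self) -> np.ndarray:
        """4x4 world-space transform (applied about the volume center)."""
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = np.eye(4)
        m[:3, :3] = self.scale * (Rz @ Ry @ Rx)
        m[:3, 3] = self.translation_mm
        return m


def _resampling_matrix(params: AugmentParams, grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space matrix/offset mapping output indices to input indices."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    center = origin + (np.asarray(grid.shape) - 1) / 2.0 * spacing
    m = params.matrix()
    inv_rot = np.linalg.inv(m[:3, :3])
    # out_world = rot @ (in_world - center) + center + t, so the sample point
    # is in_world = inv_rot @ (out_world - center - t) + center; composing
    # with index <-> world maps gives an affine on voxel indices.
    M = np.diag(1.0 / spacing) @ inv_rot @ np.diag(spacing)
    b = (inv_rot @ (origin - center - m[:3, 3]) + center - origin) / spacing
    return M, b


def augment(
    ct: np.ndarray,
    labels: list[np.ndarray],
    params: AugmentParams,
    grid: VolumeGrid,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply one augmentation transform to a CT and its label volumes.

    The same world-space transform (rotation about the volume center, then
    scaling and translation) is applied to all volumes; CT is interpolated
    trilinearly with -1000 HU fill, labels nearest-neighbor with 0 fill.
    Identity parameters return exact copies.
    """
    for lab in labels:
        if lab.shape != ct.shape:
            raise ValueError("ct and label volumes must share one grid")
    if params.is_identity:
        return ct.copy(), [lab.copy() for lab in labels]
    M, b = _resampling_matrix(params, grid)
    ct_out = ndimage.affine_transform(
        np.asarray(ct, dtype=float), M, offset=b, order=1, mode="constant", cval=PAD_HU
    )
    labs_out = []
    for lab in labels:
        out = ndimage.affine_transform(
            np.asarray(lab, dtype=float), M, offset=b, order=0, mode="constant", cval=0.0
        )
        if np.issubdtype(lab.dtype, np.integer):
            out = out.astype(lab.dtype)
        labs_out.append(out)
    return ct_out, labs_out


def diameter_mm_to_voxel(diameter_mm: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Scale a diameter map from mm to voxel units (mean in-plane voxel size)."""
    return np.asarray(diameter_mm) / _inplane_mm(grid)


def diameter_voxel_to_mm(diameter_vox: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Scale a diameter map from voxel units back to mm."""
    return np.asarray(diameter_vox) * _inplane_mm(grid)


def _inplane_mm(grid: VolumeGrid) -> float:
    return float((grid.spacing[0] + grid.spacing[1]) / 2.0)
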