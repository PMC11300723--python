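"""Voxel-grid geometry shared by all volumes.

World coordinates are in millimetres.  Voxel (i, j, k) with 0-based indices
has its *center* at ``origin + index * spacing``; all modules rely on this
single convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid"]


@dataclass(frozen=True)
class VolumeGrid:
    """Shape, spacing and origin of a 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).  The third axis is the axial
        (slice) direction.
    spacing : tuple of float
        Voxel size in mm along each axis.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- coordinate transforms -------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World position (mm) of voxel centers for (possibly fractional) indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world positions (mm)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of all voxel-center world positions, C-order over (i, j, k)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.index_to_world(idx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-coordinate bounding box spanned by voxel centers (lo, hi)."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Whether world points fall inside the voxel-center bounding box."""
        lo, hi = self.bounds()
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return np.all((xyz >= lo - 1e-9) & (xyz <= hi + 1e-9), axis=1)

    def affine(self) -> np.ndarray:
        """4x4 NIfTI-style affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VolumeGrid":
        """Build a grid from an axis-aligned affine (diagonal rotation part)."""
        rot = np.asarray(affine)[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("affine is not axis-aligned (oblique affines unsupported)")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError("affine has non-positive spacing on the diagonal")
        return cls(tuple(shape), tuple(spacing), tuple(np.asarray(affine)[:3, 3]))
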