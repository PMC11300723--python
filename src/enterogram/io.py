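"""Volume, annotation and configuration I/O.

Volumes travel as NIfTI-1 (.nii / .nii.gz) with axis-aligned affines; on
read they are reoriented to the canonical RAS-like axis order so world
coordinates are preserved while the in-memory index order is fixed.
Oblique affines are rejected: the supported geometry is supine axial
scanning.  Writes are atomic (temp file + rename) and gzip streams carry a
zero mtime so identical data produces identical bytes.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .embed import LabelVolumes
from .grid import VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_volumes",
    "write_label_volumes",
    "load_config",
    "write_provenance",
]

LABEL_FILES = {
    "segmentation": "seg.nii.gz",
    "diameter": "diameter.nii.gz",
    "longitude": "longitude.nii.gz",
}


def read_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI volume; returns (data, grid) in canonical orientation.

    The file's affine must be axis-aligned up to permutation and flips;
    oblique acquisitions are rejected explicitly.
    """
    img = nib.load(str(path))
    rot = img.affine[:3, :3]
    # each row/column must contain exactly one nonzero entry
    nonzero = np.abs(rot) > 1e-6 * np.abs(rot).max()
    if not (np.all(nonzero.sum(axis=0) == 1) and np.all(nonzero.sum(axis=1) == 1)):
        raise ValueError(
            f"{path}: oblique affine (not axis-aligned up to permutation/flip); "
            "only supine axial volumes are supported"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    grid = VolumeGrid.from_affine(data.shape, img.affine)
    return data, grid


def _atomic_bytes(path: Path, payload: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_volume(field: np.ndarray, grid: VolumeGrid, path, dtype=None) -> None:
    """Write a volume as NIfTI-1 with the grid's affine, atomically.

    ``.nii.gz`` outputs are compressed with a fixed (zero) gzip timestamp so
    repeated writes of the same data are bit-identical.
    """
    path = Path(path)
    data = np.asarray(field)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine())
    img.header.set_zooms(grid.spacing)
    payload = img.to_bytes()
    if path.name.endswith(".gz"):
        payload = gzip.compress(payload, compresslevel=6, mtime=0)
    _atomic_bytes(path, payload)


def write_label_volumes(volumes: LabelVolumes, out_dir, prefix: str = "") -> None:
    """Write the label triple as three co-registered NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(
        volumes.segmentation, volumes.grid, out_dir / (prefix + LABEL_FILES["segmentation"]), np.uint8
    )
    write_volume(
        volumes.diameter, volumes.grid, out_dir / (prefix + LABEL_FILES["diameter"]), np.float32
    )
    write_volume(
        volumes.longitude, volumes.grid, out_dir / (prefix + LABEL_FILES["longitude"]), np.float32
    )


def read_label_volumes(in_dir, prefix: str = "") -> LabelVolumes:
    in_dir = Path(in_dir)
    seg, grid = read_volume(in_dir / (prefix + LABEL_FILES["segmentation"]))
    diam, _ = read_volume(in_dir / (prefix + LABEL_FILES["diameter"]))
    lon, _ = read_volume(in_dir / (prefix + LABEL_FILES["longitude"]))
    return LabelVolumes(
        np.asarray(seg).astype(np.uint8),
        np.asarray(diam, dtype=float),
        np.asarray(lon, dtype=float),
        grid,
    )


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration for provenance sidecars."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_dir, command: str, cfg: dict, seed: int | None) -> None:
    """Record what produced the outputs of a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "command": command,
        "seed": seed,
        "config": cfg,
        "config_hash": config_hash(cfg),
    }
    _atomic_bytes(out_dir / "provenance.json", (json.dumps(doc, indent=1, sort_keys=True, default=str) + "\n").encode())
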