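"""Diameter-vs-longitude curves and the dilated-bowel decision rule.

The segmented volume and mean diameter are accumulated over 1-unit bins of
longitude.  Assuming each bin is a cylinder of volume V and diameter D, its
length follows from the change of variables

    L = (4 / pi) * V / D**2

which turns the longitude axis into a physical length axis.  Plotting
diameter against cumulative length shows dilation upstream of an
obstruction and the transition point where the diameter drops.

A query point is called *dilated small bowel* when it falls inside the
predicted segmentation, its diameter exceeds 30 mm, and its longitude lies
strictly between 40 (ligament of Treitz) and 80 (ileocecal valve);
*nondilated small bowel* is the same with diameter below 30 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import MAX_LONGITUDE, MIN_LONGITUDE, organ_initial_longitude
from .embed import LabelVolumes

__all__ = [
    "DIAMETER_THRESHOLD_MM",
    "TREITZ_LONGITUDE",
    "ILEOCECAL_LONGITUDE",
    "QueryPoint",
    "LongitudeProfile",
    "bin_by_longitude",
    "length_from_bin",
    "diameter_vs_length",
    "classify_query_point",
]

#: Clinical threshold for abnormal small-bowel dilation.
DIAMETER_THRESHOLD_MM = 30.0
#: Longitude of the ligament of Treitz (start of small bowel proper).
TREITZ_LONGITUDE = 40.0
#: Longitude of the ileocecal valve (end of small bowel).
ILEOCECAL_LONGITUDE = 80.0


@dataclass
class QueryPoint:
    """A centerline location used as a reference-standard sample.

    The measured diameter comes from annotation; the presumed longitude is
    the midpoint of the organ's decade (initial + 5), mirroring the fact
    that a point's true longitude inside an organ cannot be measured.
    """

    position: np.ndarray
    organ: str
    measured_diameter_mm: float
    presumed_longitude: float = field(default=None)  # type: ignore[assignment]
    in_mask: bool | None = None
    predicted_diameter_mm: float | None = None
    predicted_longitude: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.presumed_longitude is None:
            self.presumed_longitude = organ_initial_longitude(self.organ) + 5.0


def query_points_to_frame(points: list[QueryPoint]) -> pd.DataFrame:
    rows = []
    for q in points:
        rows.append(
            {
                "x_mm": q.position[0],
                "y_mm": q.position[1],
                "z_mm": q.position[2],
                "organ": q.organ,
                "measured_diameter_mm": q.measured_diameter_mm,
                "presumed_longitude": q.presumed_longitude,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "x_mm",
            "y_mm",
            "z_mm",
            "organ",
            "measured_diameter_mm",
            "presumed_longitude",
        ],
    )


def query_points_from_frame(df: pd.DataFrame) -> list[QueryPoint]:
    return [
        QueryPoint(
            np.array([r.x_mm, r.y_mm, r.z_mm]),
            r.organ,
            float(r.measured_diameter_mm),
            float(r.presumed_longitude),
        )
        for r in df.itertuples()
    ]


@dataclass
class LongitudeProfile:
    """Per-1-unit-longitude bins of segmented volume and mean diameter.

    ``mean_diameter_mm`` is NaN for empty bins; such bins carry zero volume
    and zero derived length and are excluded from curves.
    """

    bin_lo: np.ndarray  # left edge of each [b, b+1) bin
    volume_mm3: np.ndarray
    mean_diameter_mm: np.ndarray
    length_mm: np.ndarray
    cum_length_mm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_lo,
                "bin_hi": self.bin_lo + 1.0,
                "volume_mm3": self.volume_mm3,
                "mean_diameter_mm": self.mean_diameter_mm,
                "length_mm": self.length_mm,
                "cum_length_mm": self.cum_length_mm,
            }
        )

    @property
    def total_volume_mm3(self) -> float:
        return float(self.volume_mm3.sum())


def length_from_bin(volume_mm3: float, diameter_mm: float) -> float:
    """Cylinder length (mm) of a bin: L = 4 V / (pi D^2).

    Zero volume gives zero length; positive volume with a non-positive
    diameter is rejected.
    """
    if volume_mm3 == 0:
        return 0.0
    if diameter_mm <= 0 or not math.isfinite(diameter_mm):
        raise ValueError(
            f"positive volume {volume_mm3} with non-positive diameter {diameter_mm}"
        )
    return 4.0 / math.pi * volume_mm3 / diameter_mm**2


def bin_by_longitude(volumes: LabelVolumes) -> LongitudeProfile:
    """Bin a masked label triple into 1-unit longitude intervals.

    Per bin [b, b+1): V is the count of mask voxels whose longitude falls in
    the bin times the voxel volume; D is the unweighted mean of those
    voxels' diameters.  The sum of V over bins equals the total segmented
    volume exactly.
    """
    volumes.validate_support()
    edges = np.arange(MIN_LONGITUDE, MAX_LONGITUDE + 2.0)  # 10, 11, ..., 151
    bin_lo = edges[:-1]
    mask = volumes.mask
    lon = volumes.longitude[mask]
    diam = volumes.diameter[mask]
    # digitize into [b, b+1); longitude == 150 lands in the last bin [150, 151)
    which = np.clip(np.floor(lon - MIN_LONGITUDE).astype(int), 0, len(bin_lo) - 1)
    counts = np.bincount(which, minlength=len(bin_lo))
    vol = counts * volumes.grid.voxel_volume
    dsum = np.bincount(which, weights=diam, minlength=len(bin_lo))
    with np.errstate(invalid="ignore"):
        mean_d = np.where(counts > 0, dsum / np.maximum(counts, 1), np.nan)
    length = np.array(
        [
            length_from_bin(v, d) if c > 0 else 0.0
            for v, d, c in zip(vol, mean_d, counts)
        ]
    )
    return LongitudeProfile(bin_lo, vol, mean_d, length, np.cumsum(length))


@dataclass
class ProfileSeries:
    """Plot-ready diameter-vs-length series with reference marks."""

    x_mm: np.ndarray  # cumulative length at each nonempty bin
    diameter_mm: np.ndarray
    longitude: np.ndarray
    treitz_x_mm: float  # cumulative-length position of longitude 40
    ileocecal_x_mm: float  # cumulative-length position of longitude 80
    threshold_mm: float = DIAMETER_THRESHOLD_MM


def diameter_vs_length(profile: LongitudeProfile) -> ProfileSeries:
    """Diameter against cumulative length, with the Treitz/ileocecal marks.

    The x axis starts at 0 at longitude 10 and advances by each bin's
    derived length; the two anatomic landmarks are mapped to their
    cumulative-length positions and the 30 mm dilation threshold is carried
    as the horizontal mark.
    """
    nonempty = ~np.isnan(profile.mean_diameter_mm)
    cum = profile.cum_length_mm

    def _mark(longitude: float) -> float:
        i = int(np.searchsorted(profile.bin_lo, longitude))
        return float(cum[i - 1]) if i > 0 else 0.0

    return ProfileSeries(
        x_mm=cum[nonempty],
        diameter_mm=profile.mean_diameter_mm[nonempty],
        longitude=profile.bin_lo[nonempty] + 0.5,
        treitz_x_mm=_mark(TREITZ_LONGITUDE),
        ileocecal_x_mm=_mark(ILEOCECAL_LONGITUDE),
    )


def classify_query_point(volumes: LabelVolumes, point: QueryPoint) -> dict:
    """Sample predictions at a query point and apply the joint criteria.

    Values are read at the nearest voxel.  ``dilated_small_bowel`` requires
    inclusion in the mask, diameter strictly above 30 mm and longitude
    strictly between 40 and 80; ``nondilated_small_bowel`` is the same with
    diameter strictly below 30 mm.  A diameter of exactly 30 mm satisfies
    neither.
    """
    idx = np.rint(volumes.grid.world_to_index(point.position)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(volumes.grid.shape)):
        raise ValueError(
            f"query point {point.position} falls outside the grid {volumes.grid.shape}"
        )
    i, j, k = idx
    in_mask = bool(volumes.segmentation[i, j, k])
    d = float(volumes.diameter[i, j, k])
    lon = float(volumes.longitude[i, j, k])
    small_bowel = TREITZ_LONGITUDE < lon < ILEOCECAL_LONGITUDE
    return {
        "in_mask": in_mask,
        "predicted_diameter_mm": d,
        "predicted_longitude": lon,
        "dilated_small_bowel": in_mask and d > DIAMETER_THRESHOLD_MM and small_bowel,
        "nondilated_small_bowel": in_mask
        and d < DIAMETER_THRESHOLD_MM
        and small_bowel,
    }
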