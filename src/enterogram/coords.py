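"""The continuous gastrointestinal "longitude" coordinate.

Each of the 15 organs of the GI tract is assigned a decade of longitude
(esophagus starts at 10, stomach at 20, ... anus at 150).  Within an organ
the coordinate is interpolated proportionally to arc length:

    longitude = L0 + (L1 - L0) * s / S

where ``L0``/``L1`` are the organ's initial/final longitudes (``L1 = L0 +
10``), ``s`` is cumulative arc length from the organ's proximal end, and
``S`` is the organ's total annotated length.  A point 5 cm from the start of
a 25 cm stomach therefore sits at longitude 22; 5 cm from its end, at 28.

Organs annotated in several pieces (typically jejunum and ileum) are chained
in the order that minimises the Euclidean gaps between consecutive segment
endpoints before longitudes are assigned; gaps do not count toward arc
length, so anatomy that is continuous in longitude but discontiguous in
space (ostomies, terminal ileum vs. appendix) is handled naturally.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = [
    "ORGAN_TABLE",
    "ORGAN_NAMES",
    "SMALL_BOWEL_ORGANS",
    "organ_initial_longitude",
    "CenterlineSegment",
    "AnnotationSet",
    "order_small_bowel_segments",
    "assign_longitudes",
]

logger = logging.getLogger(__name__)

#: Initial longitude of each organ, in anatomic order.  The final longitude
#: of each organ is the next organ's initial longitude (i.e. initial + 10).
ORGAN_TABLE: dict[str, float] = {
    "Esophagus": 10,
    "Stomach": 20,
    "Duodenum": 30,
    "Treitz Jejunum": 40,
    "Jejunum": 50,
    "Ileum": 60,
    "Terminal Ileum": 70,
    "Appendix": 80,
    "Cecum": 90,
    "Ascending Colon": 100,
    "Transverse Colon": 110,
    "Descending Colon": 120,
    "Sigmoid Colon": 130,
    "Rectum": 140,
    "Anus": 150,
}

ORGAN_NAMES: tuple[str, ...] = tuple(ORGAN_TABLE)

#: Organs that are routinely annotated as several discontiguous segments.
SMALL_BOWEL_ORGANS: frozenset[str] = frozenset(
    {"Treitz Jejunum", "Jejunum", "Ileum", "Terminal Ileum"}
)

#: The longitude coordinate is clipped at the anus.
MAX_LONGITUDE = 150.0
MIN_LONGITUDE = 10.0
ORGAN_SPAN = 10.0


def organ_initial_longitude(organ: str) -> float:
    """Initial longitude of *organ*; its final longitude is initial + 10."""
    try:
        return float(ORGAN_TABLE[organ])
    except KeyError:
        raise KeyError(f"unknown organ name: {organ!r}") from None


@dataclass
class CenterlineSegment:
    """An ordered run of centerline points with per-point diameters.

    ``points`` are world positions in mm, ``diameters`` the bowel outer
    diameter in mm at each point.  ``longitudes`` is populated by
    :func:`assign_longitudes`.
    """

    points: np.ndarray
    diameters: np.ndarray
    organ: str
    longitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of mm positions")
        if len(self.points) < 2:
            raise ValueError("a centerline segment needs at least 2 points")
        if self.diameters.shape != (len(self.points),):
            raise ValueError("diameters must be one value per point")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must all be positive")
        if self.organ not in ORGAN_TABLE:
            raise KeyError(f"unknown organ name: {self.organ!r}")
        if self.longitudes is not None:
            self.longitudes = np.asarray(self.longitudes, dtype=float)
            if self.longitudes.shape != (len(self.points),):
                raise ValueError("longitudes must be one value per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]

    def edge_lengths(self) -> np.ndarray:
        """Length in mm of each piecewise-linear edge."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at each point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths())])

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return float(self.edge_lengths().sum())

    def reversed(self) -> "CenterlineSegment":
        lon = None if self.longitudes is None else self.longitudes[::-1].copy()
        return CenterlineSegment(
            self.points[::-1].copy(), self.diameters[::-1].copy(), self.organ, lon
        )


@dataclass
class AnnotationSet:
    """Centerline annotations of one scan, tied to its voxel grid."""

    segments: list[CenterlineSegment]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        for seg in self.segments:
            inside = self.grid.contains(seg.points)
            if not np.all(inside):
                bad = seg.points[~inside][0]
                raise ValueError(
                    f"segment of {seg.organ!r} has point {bad} outside the grid bounds"
                )

    def organs(self) -> list[str]:
        """Organs present, in anatomic order."""
        present = {s.organ for s in self.segments}
        return [o for o in ORGAN_NAMES if o in present]

    def by_organ(self, organ: str) -> list[CenterlineSegment]:
        return [s for s in self.segments if s.organ == organ]

    @property
    def has_longitudes(self) -> bool:
        return all(s.longitudes is not None for s in self.segments)

    # -- JSON round trip --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "organ": s.organ,
                    "points": s.points.tolist(),
                    "diameters_mm": s.diameters.tolist(),
                    **(
                        {"longitudes": s.longitudes.tolist()}
                        if s.longitudes is not None
                        else {}
                    ),
                }
                for s in self.segments
            ],
            "grid": {
                "shape": list(self.grid.shape),
                "spacing_mm": list(self.grid.spacing),
                "origin_mm": list(self.grid.origin),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        grid = VolumeGrid(
            tuple(d["grid"]["shape"]),
            tuple(d["grid"]["spacing_mm"]),
            tuple(d["grid"]["origin_mm"]),
        )
        segs = [
            CenterlineSegment(
                np.asarray(s["points"], dtype=float),
                np.asarray(s["diameters_mm"], dtype=float),
                s["organ"],
                None if "longitudes" not in s else np.asarray(s["longitudes"]),
            )
            for s in d["segments"]
        ]
        return cls(segs, grid)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnnotationSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# segment ordering
# ---------------------------------------------------------------------------

EXHAUSTIVE_LIMIT = 8


def _endpoint_gap_matrix(segments: list[CenterlineSegment]) -> np.ndarray:
    """gap[i, oi, j, oj]: distance from the tail of i (orientation oi) to the
    head of j (orientation oj).  Orientation 0 keeps the stored point order,
    1 reverses it."""
    n = len(segments)
    heads = np.empty((n, 2, 3))
    tails = np.empty((n, 2, 3))
    for i, s in enumerate(segments):
        heads[i, 0], tails[i, 0] = s.head, s.tail
        heads[i, 1], tails[i, 1] = s.tail, s.head
    diff = tails[:, :, None, None, :] - heads[None, None, :, :, :]
    return np.linalg.norm(diff, axis=-1)


def _chain_cost(
    gap: np.ndarray,
    perm: tuple[int, ...],
    anchor_gap: np.ndarray | None,
) -> tuple[float, tuple[int, ...]]:
    """Min total gap over orientations for a fixed permutation (exact DP)."""
    # cost[o] = best cost of the chain so far ending with last segment in
    # orientation o; ties prefer orientation 0 for determinism.
    n = len(perm)
    if anchor_gap is not None:
        cost = anchor_gap[perm[0]].astype(float).copy()
    else:
        cost = np.zeros(2)
    back: list[np.ndarray] = []
    for k in range(1, n):
        step = gap[perm[k - 1], :, perm[k], :]  # (o_prev, o_next)
        tot = cost[:, None] + step
        choice = np.argmin(tot, axis=0)
        back.append(choice)
        cost = tot[choice, [0, 1]]
    o_last = int(np.argmin(cost))
    total = float(cost[o_last])
    flips = [o_last]
    for choice in reversed(back):
        flips.append(int(choice[flips[-1]]))
    flips.reverse()
    return total, tuple(flips)


def order_small_bowel_segments(
    segments: list[CenterlineSegment],
    anchor: np.ndarray | None = None,
) -> tuple[tuple[int, ...], tuple[bool, ...]]:
    """Chain same-organ segments so consecutive endpoint gaps are minimal.

    Returns the permutation of input indices and, per chained position, a
    flag saying whether that segment is traversed in reverse.  The objective
    is the open-path sum of gaps between each segment's exit endpoint and
    the next segment's entry endpoint; if *anchor* (a world point, e.g. the
    end of the previous organ) is given, the gap from the anchor to the
    first entry endpoint is included so the chain starts near it.

    Exhaustive over all permutations (orientations resolved exactly by
    dynamic programming) for up to 8 segments; greedy nearest-endpoint
    chaining beyond that.  Ties break toward lower input index and unflipped
    orientation.
    """
    if len(segments) == 0:
        raise ValueError("cannot order an empty list of segments")
    organs = {s.organ for s in segments}
    if len(organs) > 1:
        raise ValueError(f"segments must share one organ, got {sorted(organs)}")
    n = len(segments)
    if n == 1:
        if anchor is not None:
            d0 = np.linalg.norm(segments[0].head - anchor)
            d1 = np.linalg.norm(segments[0].tail - anchor)
            return (0,), (d1 < d0,)
        return (0,), (False,)

    gap = _endpoint_gap_matrix(segments)
    anchor_gap = None
    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        heads = np.array(
            [[s.head, s.tail] for s in segments]
        )  # (n, 2, 3): entry endpoint per orientation
        anchor_gap = np.linalg.norm(heads - anchor, axis=-1)

    if n <= EXHAUSTIVE_LIMIT:
        best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None
        for perm in itertools.permutations(range(n)):
            total, flips = _chain_cost(gap, perm, anchor_gap)
            if best is None or total < best[0] - 1e-12:
                best = (total, perm, flips)
        assert best is not None
        return best[1], tuple(bool(f) for f in best[2])

    # greedy nearest-endpoint chaining
    remaining = set(range(n))
    if anchor_gap is not None:
        flat = np.argmin(anchor_gap)
        first, o_first = divmod(int(flat), 2)
    else:
        first, o_first = 0, 0
    perm_l = [first]
    flips_l = [o_first]
    remaining.discard(first)
    while remaining:
        i, oi = perm_l[-1], flips_l[-1]
        cands = sorted(remaining)
        sub = gap[i, oi][cands]  # (m, 2)
        flat = int(np.argmin(sub))
        j, oj = cands[flat // 2], flat % 2
        perm_l.append(j)
        flips_l.append(oj)
        remaining.discard(j)
    return tuple(perm_l), tuple(bool(f) for f in flips_l)


# ---------------------------------------------------------------------------
# longitude assignment
# ---------------------------------------------------------------------------


def assign_longitudes(annotations: AnnotationSet) -> AnnotationSet:
    """Assign a longitude to every centerline point, organ by organ.

    Within each organ, segments are chained (multi-segment organs via
    :func:`order_small_bowel_segments`, anchored at the previous organ's
    terminal point) and longitude increases proportionally to cumulative arc
    length from ``L0`` to ``L0 + 10``.  Inter-segment gaps contribute no
    arc length.  Values are clipped to the coordinate's terminal value 150.

    Returns a new :class:`AnnotationSet` whose segments are stored in chained
    anatomic order with ``longitudes`` populated.
    """
    out_segments: list[CenterlineSegment] = []
    prev_end: np.ndarray | None = None
    for organ in annotations.organs():
        segs = annotations.by_organ(organ)
        perm, flips = order_small_bowel_segments(segs, anchor=prev_end)
        chained = [
            segs[i].reversed() if flip else segs[i] for i, flip in zip(perm, flips)
        ]
        total = sum(s.length for s in chained)
        if total <= 0:
            raise ValueError(f"organ {organ!r} has zero total arc length")
        L0 = organ_initial_longitude(organ)
        s_offset = 0.0
        for seg in chained:
            s = s_offset + seg.arc_lengths()
            lon = np.minimum(L0 + ORGAN_SPAN * s / total, MAX_LONGITUDE)
            out_segments.append(
                CenterlineSegment(seg.points.copy(), seg.diameters.copy(), organ, lon)
            )
            s_offset += seg.length
        prev_end = chained[-1].tail
    return AnnotationSet(out_segments, annotations.grid)
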