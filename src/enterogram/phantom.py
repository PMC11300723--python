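"""Synthetic CT phantoms of the gastrointestinal tract.

The generator emulates an annotated abdominal CT at configurable scale: one
smooth random tube per organ, chained in anatomic order inside the volume,
with per-point diameters, exact longitude assignment, a rendered
Hounsfield-unit field (lumen contrast vs. soft-tissue background plus
noise) and the reference-standard query points of the evaluation protocol
(one per organ plus four each for jejunum and ileum).

With an obstruction configured, small-bowel diameters upstream of the
transition longitude take a dilated value (> 30 mm) and fall back to the
base calibre downstream, smoothed over a short arc length so the
diameter-vs-longitude curve shows a realistic transition point.

All randomness is driven by explicit integer seeds; the ground-truth label
volumes are exactly ``embed_annotations`` applied to the generated
annotations, so every downstream stage can be tested against exact truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coords import (
    ORGAN_NAMES,
    ORGAN_SPAN,
    SMALL_BOWEL_ORGANS,
    AnnotationSet,
    CenterlineSegment,
    assign_longitudes,
    organ_initial_longitude,
)
from .embed import LabelVolumes, embed_annotations
from .grid import VolumeGrid
from .profile import (
    DIAMETER_THRESHOLD_MM,
    ILEOCECAL_LONGITUDE,
    TREITZ_LONGITUDE,
    QueryPoint,
)

__all__ = [
    "Obstruction",
    "PhantomConfig",
    "PhantomSample",
    "generate_centerline",
    "render_ct",
    "sample_query_points",
    "generate_sample",
]

logger = logging.getLogger(__name__)

HU_AIR = -1000.0
HU_FLUID = 10.0
HU_ENTERIC_CONTRAST = 300.0
HU_SOFT_TISSUE = 40.0
HU_MIN, HU_MAX = -1024.0, 3071.0

#: Default organs included at desk scale: stomach through cecum, spanning
#: longitudes 20-100 so query points bracket the small bowel.
DEFAULT_ORGANS: tuple[str, ...] = (
    "Stomach",
    "Duodenum",
    "Treitz Jejunum",
    "Jejunum",
    "Ileum",
    "Terminal Ileum",
    "Cecum",
)

#: Target annotated arc length (mm) per organ for the miniature phantom.
DEFAULT_ORGAN_LENGTH_MM: dict[str, float] = {
    "Esophagus": 80.0,
    "Stomach": 120.0,
    "Duodenum": 110.0,
    "Treitz Jejunum": 120.0,
    "Jejunum": 170.0,
    "Ileum": 170.0,
    "Terminal Ileum": 90.0,
    "Appendix": 40.0,
    "Cecum": 60.0,
    "Ascending Colon": 100.0,
    "Transverse Colon": 120.0,
    "Descending Colon": 100.0,
    "Sigmoid Colon": 100.0,
    "Rectum": 60.0,
    "Anus": 30.0,
}

#: Lumen attenuation per organ: fluid-attenuation contents for the upper
#: tract and small bowel, gas for the colon.
DEFAULT_LUMEN_HU: dict[str, float] = {
    **{o: HU_FLUID for o in ORGAN_NAMES},
    **{
        o: HU_AIR
        for o in (
            "Cecum",
            "Ascending Colon",
            "Transverse Colon",
            "Descending Colon",
            "Sigmoid Colon",
            "Rectum",
        )
    },
}

#: Query-point protocol: one point per organ, four for jejunum and ileum.
DEFAULT_QUERY_COUNTS: dict[str, int] = {"Jejunum": 4, "Ileum": 4}

#: Supine anatomic layout: the typical region each organ occupies, as
#: fractions of the volume extent along (x: right->left, y: anterior->
#: posterior, z: inferior->superior).  The tube's random walk is attracted
#: toward its organ's region, so longitude correlates with position the way
#: it does in a real abdomen (anatomic landmarks are what make position
#: along the tract inferable from CT).
ORGAN_ANCHOR_FRACTION: dict[str, tuple[float, float, float]] = {
    "Esophagus": (0.45, 0.55, 0.95),
    "Stomach": (0.30, 0.40, 0.80),
    "Duodenum": (0.50, 0.50, 0.65),
    "Treitz Jejunum": (0.40, 0.45, 0.60),
    "Jejunum": (0.35, 0.50, 0.45),
    "Ileum": (0.55, 0.55, 0.35),
    "Terminal Ileum": (0.70, 0.55, 0.25),
    "Appendix": (0.80, 0.55, 0.15),
    "Cecum": (0.80, 0.50, 0.20),
    "Ascending Colon": (0.85, 0.45, 0.45),
    "Transverse Colon": (0.50, 0.35, 0.70),
    "Descending Colon": (0.15, 0.45, 0.45),
    "Sigmoid Colon": (0.25, 0.55, 0.20),
    "Rectum": (0.50, 0.70, 0.12),
    "Anus": (0.50, 0.70, 0.05),
}


@dataclass(frozen=True)
class Obstruction:
    """A small-bowel obstruction: dilation upstream of the transition."""

    transition_longitude: float
    dilated_diameter_mm: float = 40.0

    def __post_init__(self) -> None:
        if not (TREITZ_LONGITUDE < self.transition_longitude < ILEOCECAL_LONGITUDE):
            raise ValueError(
                "transition longitude must lie in the small bowel "
                f"({TREITZ_LONGITUDE}, {ILEOCECAL_LONGITUDE}), "
                f"got {self.transition_longitude}"
            )
        if self.dilated_diameter_mm <= DIAMETER_THRESHOLD_MM:
            raise ValueError(
                f"dilated diameter must exceed {DIAMETER_THRESHOLD_MM} mm, "
                f"got {self.dilated_diameter_mm}"
            )


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to synthesize one annotated scan."""

    grid: VolumeGrid = VolumeGrid((32, 32, 32), (5.0, 5.0, 5.0))
    organs: tuple[str, ...] = DEFAULT_ORGANS
    organ_length_scale: float = 0.85
    base_diameter_range_mm: tuple[float, float] = (16.0, 24.0)
    obstruction: Obstruction | None = None
    lumen_hu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LUMEN_HU))
    background_hu: float = HU_SOFT_TISSUE
    noise_sd_hu: float = 10.0
    transition_smoothing_mm: float = 20.0
    step_mm: float = 6.0
    split_small_bowel: bool = True
    fold_texture: bool = True

    def __post_init__(self) -> None:
        for o in self.organs:
            if o not in ORGAN_NAMES:
                raise KeyError(f"unknown organ name: {o!r}")
        lo, hi = self.base_diameter_range_mm
        if not (0 < lo <= hi):
            raise ValueError(f"bad base diameter range {self.base_diameter_range_mm}")


@dataclass
class PhantomSample:
    """One synthetic scan with exact ground truth."""

    ct: np.ndarray
    truth: LabelVolumes
    annotations: AnnotationSet
    query_points: list[QueryPoint]
    config: PhantomConfig


# ---------------------------------------------------------------------------
# centerline geometry
# ---------------------------------------------------------------------------


def _random_tube(
    rng: np.random.Generator,
    start: np.ndarray,
    length_mm: float,
    step_mm: float,
    lo: np.ndarray,
    hi: np.ndarray,
    anchor: np.ndarray | None = None,
    attraction: float = 0.9,
) -> np.ndarray:
    """Smooth random walk of the requested arc length inside a box.

    The walk direction performs a spherical random walk (correlated between
    steps so curvature stays gentle relative to tube radius); positions are
    kept inside [lo, hi] by reflecting the direction at the walls.  When an
    *anchor* is given the direction is additionally attracted toward it, so
    the tube coils in its organ's anatomic region.
    """
    n = max(int(np.ceil(length_mm / step_mm)), 2)
    pos = np.asarray(start, dtype=float).copy()
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [pos.copy()]
    for _ in range(n):
        d = d + 0.55 * rng.normal(size=3)
        if anchor is not None:
            pull = anchor - pos
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                # stronger pull when far from the organ's region
                d = d + attraction * min(norm / (4 * step_mm), 2.0) * pull / norm
        d /= np.linalg.norm(d)
        nxt = pos + step_mm * d
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                d[ax] = -d[ax]
        nxt = np.clip(pos + step_mm * d, lo, hi)
        # avoid degenerate zero-length edges if clipped into a corner
        if np.linalg.norm(nxt - pos) < 1e-6:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            nxt = np.clip(pos + step_mm * d, lo, hi)
        pos = nxt
        pts.append(pos.copy())
    return np.asarray(pts)


def _diameter_profile(
    longitudes: np.ndarray,
    base_mm: float,
    obstruction: Obstruction | None,
    smoothing_lon: float,
) -> np.ndarray:
    """Diameter at each longitude: dilated upstream of the transition."""
    d = np.full_like(longitudes, base_mm, dtype=float)
    if obstruction is None:
        return d
    t = obstruction.transition_longitude
    w = max(smoothing_lon, 1e-6)
    # ramp from dilated (longitude <= t - w) down to base (longitude >= t),
    # restricted to the small bowel (>= ligament of Treitz)
    ramp = np.clip((t - longitudes) / w, 0.0, 1.0)
    ramp[longitudes < TREITZ_LONGITUDE] = 0.0
    return d + ramp * (obstruction.dilated_diameter_mm - base_mm)


def generate_centerline(config: PhantomConfig, seed: int) -> AnnotationSet:
    """Generate annotated centerlines for every configured organ.

    Organs are laid out as consecutive smooth tubes (each starting where the
    previous ended), small-bowel organs optionally split into two
    discontiguous segments, and longitudes assigned exactly as for real
    annotations.  Per-point diameters follow the organ's base calibre (drawn
    from the configured range) modulated by gentle along-tube variation and,
    when an obstruction is configured, by upstream dilation.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid
    glo, ghi = grid.bounds()
    max_diam = (
        config.obstruction.dilated_diameter_mm
        if config.obstruction
        else config.base_diameter_range_mm[1]
    )
    margin = max_diam / 2.0 + float(max(grid.spacing))
    lo, hi = glo + margin, ghi - margin
    if np.any(hi <= lo):
        raise ValueError(
            f"grid extent {ghi - glo} mm too small for tube diameter {max_diam} mm"
        )

    organs = [o for o in ORGAN_NAMES if o in config.organs]
    anchors = {
        o: lo + np.asarray(ORGAN_ANCHOR_FRACTION[o]) * (hi - lo) for o in organs
    }
    first_anchor = anchors[organs[0]]
    start = np.clip(
        first_anchor + rng.normal(scale=0.05 * (hi - lo), size=3), lo, hi
    )
    raw_segments: list[CenterlineSegment] = []
    for organ in organs:
        pts = _random_tube(
            rng,
            start,
            config.organ_length_scale * DEFAULT_ORGAN_LENGTH_MM[organ],
            config.step_mm,
            lo,
            hi,
            anchor=anchors[organ],
        )
        start = pts[-1].copy()
        dummy = np.ones(len(pts))
        if (
            config.split_small_bowel
            and organ in SMALL_BOWEL_ORGANS
            and len(pts) >= 7
        ):
            cut = len(pts) // 2
            # drop one walk point so the two segments are discontiguous
            parts = [(pts[:cut], dummy[:cut]), (pts[cut + 1 :], dummy[cut + 1 :])]
            if rng.random() < 0.5:  # present segments out of order
                parts.reverse()
            for p, dd in parts:
                if rng.random() < 0.5:
                    p, dd = p[::-1], dd[::-1]
                raw_segments.append(CenterlineSegment(p.copy(), dd.copy(), organ))
        else:
            raw_segments.append(CenterlineSegment(pts, dummy, organ))

    with_lon = assign_longitudes(AnnotationSet(raw_segments, grid))

    # diameters from the assigned longitudes
    base_by_organ = {
        o: rng.uniform(*config.base_diameter_range_mm) for o in organs
    }
    smoothing_lon = {
        o: ORGAN_SPAN
        * config.transition_smoothing_mm
        / max(sum(s.length for s in with_lon.by_organ(o)), 1e-9)
        for o in organs
    }
    final: list[CenterlineSegment] = []
    for seg in with_lon.segments:
        d = _diameter_profile(
            seg.longitudes,
            base_by_organ[seg.organ],
            config.obstruction if seg.organ in SMALL_BOWEL_ORGANS else None,
            smoothing_lon[seg.organ],
        )
        wobble = 1.0 + 0.05 * np.sin(
            seg.longitudes * 2.1 + rng.uniform(0, 2 * np.pi)
        )
        final.append(
            CenterlineSegment(seg.points, d * wobble, seg.organ, seg.longitudes)
        )
    return AnnotationSet(final, grid)


# ---------------------------------------------------------------------------
# CT rendering and query points
# ---------------------------------------------------------------------------


def _organ_of_longitude(lon: np.ndarray) -> np.ndarray:
    """Organ index (into ORGAN_NAMES) for each longitude value."""
    idx = np.floor((lon - 10.0) / ORGAN_SPAN).astype(int)
    return np.clip(idx, 0, len(ORGAN_NAMES) - 1)


#: Mucosal fold texture: (amplitude HU, wavelength mm) per organ.  Jejunal
#: plicae circulares are dense and prominent, the ileum is comparatively
#: featureless, colonic haustra are coarse, gastric rugae intermediate —
#: the fold pattern is the local cue radiologists use to tell bowel
#: segments apart.
ORGAN_FOLDS_HU_MM: dict[str, tuple[float, float]] = {
    "Esophagus": (0.0, 1.0),
    "Stomach": (50.0, 18.0),
    "Duodenum": (60.0, 9.0),
    "Treitz Jejunum": (70.0, 8.0),
    "Jejunum": (70.0, 10.0),
    "Ileum": (20.0, 14.0),
    "Terminal Ileum": (35.0, 12.0),
    "Appendix": (0.0, 1.0),
    "Cecum": (120.0, 30.0),
    "Ascending Colon": (120.0, 28.0),
    "Transverse Colon": (120.0, 26.0),
    "Descending Colon": (120.0, 24.0),
    "Sigmoid Colon": (110.0, 20.0),
    "Rectum": (60.0, 20.0),
    "Anus": (0.0, 1.0),
}


def _fold_texture(
    lon: np.ndarray, organ_idx: np.ndarray, organ_len_mm: dict[str, float]
) -> np.ndarray:
    """Periodic fold/haustral attenuation added to in-lumen voxels.

    The phase advances with arc length along the organ (recovered from the
    longitude, which is proportional to arc length within each organ), at
    the organ's fold wavelength.
    """
    out = np.zeros_like(lon, dtype=float)
    for i, organ in enumerate(ORGAN_NAMES):
        sel = organ_idx == i
        if not np.any(sel) or organ not in organ_len_mm:
            continue
        amp, wav = ORGAN_FOLDS_HU_MM[organ]
        if amp == 0:
            continue
        L0 = organ_initial_longitude(organ)
        s = (lon[sel] - L0) / ORGAN_SPAN * organ_len_mm[organ]
        out[sel] = amp * np.sin(np.pi * s / wav) ** 2
    return out


def render_ct(
    annotations: AnnotationSet,
    config: PhantomConfig,
    seed: int,
    truth: LabelVolumes | None = None,
) -> np.ndarray:
    """Render the Hounsfield-unit field for an annotated phantom.

    Lumen voxels take their organ's configured attenuation, everything else
    the soft-tissue background; zero-mean Gaussian noise of the configured
    standard deviation is added and values are clipped to the CT range.
    """
    if truth is None:
        truth = embed_annotations(annotations)
    rng = np.random.default_rng(seed)
    ct = np.full(truth.grid.shape, config.background_hu, dtype=float)
    mask = truth.mask
    lon_in = truth.longitude[mask]
    organ_idx = _organ_of_longitude(lon_in)
    lumen = np.array(
        [config.lumen_hu.get(o, DEFAULT_LUMEN_HU[o]) for o in ORGAN_NAMES]
    )
    ct[mask] = lumen[organ_idx]
    if config.fold_texture:
        organ_len = {
            o: sum(s.length for s in annotations.by_organ(o))
            for o in annotations.organs()
        }
        ct[mask] += _fold_texture(lon_in, organ_idx, organ_len)
    if config.noise_sd_hu > 0:
        ct += rng.normal(0.0, config.noise_sd_hu, size=ct.shape)
    return np.clip(ct, HU_MIN, HU_MAX)


def sample_query_points(
    annotations: AnnotationSet,
    counts: dict[str, int] | None = None,
    seed: int = 0,
) -> list[QueryPoint]:
    """Draw reference-standard query points along the annotated centerline.

    By default one point per organ present, but four each for jejunum and
    ileum (their length and importance in obstruction warrant denser
    sampling).  Each point carries the true annotated diameter as its
    measurement and the organ midpoint (initial longitude + 5) as its
    presumed longitude.  Requested organs absent from the annotations are
    skipped with a warning.
    """
    if not annotations.has_longitudes:
        raise ValueError("annotations need assigned longitudes to sample query points")
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = {o: DEFAULT_QUERY_COUNTS.get(o, 1) for o in ORGAN_NAMES}
    present = set(annotations.organs())
    points: list[QueryPoint] = []
    for organ, k in counts.items():
        if organ not in present:
            logger.warning("query-point organ %r absent from annotations; skipped", organ)
            continue
        segs = annotations.by_organ(organ)
        pts = np.concatenate([s.points for s in segs])
        diams = np.concatenate([s.diameters for s in segs])
        picks = rng.choice(len(pts), size=min(k, len(pts)), replace=False)
        for i in sorted(picks):
            points.append(QueryPoint(pts[i].copy(), organ, float(diams[i])))
    return points


def generate_sample(config: PhantomConfig, seed: int) -> PhantomSample:
    """Generate a full phantom: annotations, exact truth, CT, query points."""
    ss = np.random.SeedSequence(seed)
    s_geom, s_ct, s_query = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    annotations = generate_centerline(config, s_geom)
    truth = embed_annotations(annotations)
    ct = render_ct(annotations, config, s_ct, truth=truth)
    query = sample_query_points(annotations, seed=s_query)
    return PhantomSample(ct, truth, annotations, query, config)
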