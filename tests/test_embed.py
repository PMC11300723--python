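"""Centerline-to-volume embedding against brute-force oracles."""

import numpy as np
import pytest

from enterogram.coords import AnnotationSet, CenterlineSegment, assign_longitudes
from enterogram.embed import LabelVolumes, embed_annotations, project_to_segment
from enterogram.grid import VolumeGrid

from conftest import random_wiggly_segment, straight_segment


def _with_longitudes(segs, grid):
    return assign_longitudes(AnnotationSet(segs, grid))


def embed_oracle(annotations: AnnotationSet) -> LabelVolumes:
    """Per-voxel / per-segment exhaustive loop (the reference semantics)."""
    grid = annotations.grid
    out = LabelVolumes.zeros(grid)
    nx, ny, nz = grid.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = grid.index_to_world(np.array([i, j, k]))
                best = (np.inf, 0.0, 0.0)
                for seg in annotations.segments:
                    dist, _, diam, lon = project_to_segment(p, seg)
                    if dist < best[0]:
                        best = (dist, diam, lon)
                if best[0] <= best[1] / 2.0:
                    out.segmentation[i, j, k] = 1
                    out.diameter[i, j, k] = best[1]
                    out.longitude[i, j, k] = best[2]
    return out


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def test_projection_onto_first_point():
    grid = VolumeGrid((40, 40, 40))
    seg = _with_longitudes([straight_segment(start=(5, 10, 10))], grid).segments[0]
    dist, frac, diam, lon = project_to_segment(seg.points[0], seg)
    assert dist == 0.0
    assert frac == 0.0
    assert diam == seg.diameters[0]
    assert lon == seg.longitudes[0]


def test_projection_clamps_beyond_endpoint():
    grid = VolumeGrid((40, 40, 40))
    seg = _with_longitudes(
        [straight_segment(start=(5, 10, 10), length=20.0)], grid
    ).segments[0]
    p = np.array([30.0, 10.0, 10.0])  # 5 mm beyond the last point on-axis
    dist, frac, diam, lon = project_to_segment(p, seg)
    assert frac == pytest.approx(1.0)
    assert dist == pytest.approx(np.linalg.norm(p - seg.points[-1]))
    assert diam == pytest.approx(seg.diameters[-1])


def test_projection_matches_dense_sampling():
    """Minimum distance agrees with a 0.01 mm dense sampling of the polyline."""
    rng = np.random.default_rng(21)
    grid = VolumeGrid((40, 40, 40))
    seg = _with_longitudes([random_wiggly_segment(rng)], grid).segments[0]
    # densely resample the polyline
    dense = []
    for a, b in zip(seg.points[:-1], seg.points[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / 0.01)), 1)
        t = np.linspace(0, 1, n, endpoint=False)
        dense.append(a + t[:, None] * (b - a))
    dense.append(seg.points[-1:])
    dense = np.concatenate(dense)
    for _ in range(10):
        p = rng.uniform(0, 35, 3)
        dist, _, _, _ = project_to_segment(p, seg)
        ref = np.min(np.linalg.norm(dense - p, axis=1))
        assert dist == pytest.approx(ref, abs=0.02)


def test_interpolation_along_varying_diameter():
    grid = VolumeGrid((40, 40, 40))
    pts = np.array([[5.0, 10, 10], [15.0, 10, 10]])
    seg = _with_longitudes(
        [CenterlineSegment(pts, np.array([4.0, 8.0]), "Ileum")], grid
    ).segments[0]
    # projection foot at 1/4 of the single edge
    _, frac, diam, lon = project_to_segment(np.array([7.5, 12.0, 10.0]), seg)
    assert frac == pytest.approx(0.25)
    assert diam == pytest.approx(5.0)
    assert lon == pytest.approx(62.5)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def test_empty_annotations_embed_to_zero():
    grid = VolumeGrid((8, 8, 8))
    out = embed_annotations(AnnotationSet([], grid))
    assert out.segmentation.sum() == 0
    assert out.diameter.sum() == 0
    assert out.longitude.sum() == 0


def test_unassigned_longitudes_rejected():
    grid = VolumeGrid((20, 20, 20))
    ann = AnnotationSet([straight_segment(start=(2, 10, 10), length=15.0)], grid)
    with pytest.raises(ValueError, match="longitudes"):
        embed_annotations(ann)


def test_straight_cylinder_is_rasterized_exactly(cylinder_annotations):
    """Voxel centers within 4 mm of an 8 mm straight tube's axis carry
    segmentation 1 and diameter 8; others (away from the end caps) carry 0."""
    out = embed_annotations(cylinder_annotations)
    seg = cylinder_annotations.segments[0]
    a, b = seg.points[0], seg.points[-1]
    grid = cylinder_annotations.grid
    centers = grid.voxel_centers()
    ax = (b - a) / np.linalg.norm(b - a)
    t = (centers - a) @ ax
    radial = np.linalg.norm(centers - a - t[:, None] * ax, axis=1)
    between = (t >= 0) & (t <= np.linalg.norm(b - a))
    inside = between & (radial <= 4.0)
    got = out.segmentation.ravel().astype(bool)
    assert np.all(got[inside])
    assert np.all(out.diameter.ravel()[inside] == 8.0)
    # outside the capped tube: radial > 4 and beyond the hemispherical caps
    far = radial > 4.0
    far &= np.minimum(np.linalg.norm(centers - a, axis=1), np.linalg.norm(centers - b, axis=1)) > 4.0
    assert not np.any(got[far])


def test_support_equality(obstructed_phantom):
    obstructed_phantom.truth.validate_support()


def test_embedding_matches_per_voxel_oracle():
    """Vectorized embedding is voxelwise identical to the exhaustive loop."""
    rng = np.random.default_rng(31)
    grid = VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0))
    segs = [
        random_wiggly_segment(rng, organ=org, n_points=6, box=(30, 30, 30))
        for org in ("Jejunum", "Ileum", "Cecum")
    ]
    ann = _with_longitudes(segs, grid)
    fast = embed_annotations(ann)
    slow = embed_oracle(ann)
    np.testing.assert_array_equal(fast.segmentation, slow.segmentation)
    np.testing.assert_array_equal(fast.diameter, slow.diameter)
    np.testing.assert_array_equal(fast.longitude, slow.longitude)


def test_closest_segment_tie_goes_to_lower_index():
    grid = VolumeGrid((20, 20, 20))
    a = straight_segment(organ="Jejunum", start=(2, 8, 10), length=16, diameter=6)
    b = straight_segment(organ="Ileum", start=(2, 12, 10), length=16, diameter=6)
    ann = _with_longitudes([a, b], grid)
    out = embed_annotations(ann)
    # the mid-plane y=10 is equidistant: values must come from segment 0
    mid = out.longitude[:, 10, 10]
    lon_a = ann.segments[0].longitudes
    inside = out.segmentation[:, 10, 10] > 0
    assert np.all(mid[inside] >= lon_a.min() - 1e-9)
    assert np.all(mid[inside] <= lon_a.max() + 1e-9)


def test_cylinder_volume_converges_to_analytic():
    """An embedded D = 12 mm cylinder's voxel volume is within 5% of
    pi D^2 L / 4 at 1 mm spacing (hemispherical caps subtracted)."""
    grid = VolumeGrid((70, 26, 26), (1.0, 1.0, 1.0))
    seg = straight_segment(start=(12, 12.5, 12.5), length=45.0, diameter=12.0, n_points=4)
    out = embed_annotations(_with_longitudes([seg], grid))
    got = out.segmented_volume()
    want = np.pi * 12.0**2 / 4.0 * 45.0 + 4.0 / 3.0 * np.pi * 6.0**3
    assert got == pytest.approx(want, rel=0.05)


def test_embedding_equivariant_under_rigid_motion():
    """Translating+rotating annotations and grid together permutes nothing:
    the voxel data are identical."""
    rng = np.random.default_rng(17)
    seg = random_wiggly_segment(rng, n_points=8)
    grid = VolumeGrid((18, 18, 18), (2.0, 2.0, 2.0))
    base = embed_annotations(_with_longitudes([seg], grid))

    # rigid motion: 90 degree rotation about z plus a translation
    R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([7.0, -3.0, 11.0])
    pts2 = seg.points @ R.T + t
    seg2 = CenterlineSegment(pts2, seg.diameters.copy(), seg.organ)
    # transformed grid: same index lattice, rotated axes -> new origin/axes;
    # a 90 degree rotation maps the axis-aligned grid onto another
    # axis-aligned grid with permuted axes, here expressible by rotating the
    # origin and swapping the first two axes of the output.
    origin2 = R @ np.asarray(grid.origin) + t
    # world x' = -y, y' = x: new grid origin at x-min corresponds to y-max
    n = grid.shape[0]
    origin2[0] -= (n - 1) * grid.spacing[1]
    grid2 = VolumeGrid(grid.shape, grid.spacing, tuple(origin2))
    out2 = embed_annotations(_with_longitudes([seg2], grid2))
    # out2 axes: x' runs along -y of the original, y' along +x
    expect = np.flip(base.segmentation.transpose(1, 0, 2), axis=0)
    np.testing.assert_array_equal(out2.segmentation, expect)
    np.testing.assert_allclose(
        out2.longitude, np.flip(base.longitude.transpose(1, 0, 2), axis=0), atol=1e-9
    )
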