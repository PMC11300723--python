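import logging

import numpy as np
import pytest

from enterogram.coords import AnnotationSet, CenterlineSegment, assign_longitudes
from enterogram.grid import VolumeGrid
from enterogram.phantom import Obstruction, PhantomConfig, generate_sample

# absent-organ warnings from the reduced desk-scale organ set are expected
logging.getLogger("enterogram.phantom").setLevel(logging.ERROR)


def straight_segment(
    organ: str = "Jejunum",
    start=(5.0, 15.0, 15.0),
    direction=(1.0, 0.0, 0.0),
    length: float = 20.0,
    n_points: int = 5,
    diameter: float = 8.0,
) -> CenterlineSegment:
    """An axis-aligned straight centerline with constant diameter."""
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = np.linspace(0.0, length, n_points)
    pts = start + t[:, None] * direction
    return CenterlineSegment(pts, np.full(n_points, diameter), organ)


def random_wiggly_segment(rng, organ="Jejunum", n_points=12, box=(30.0, 30.0, 30.0)):
    """A smooth random centerline confined to a box, for oracle tests."""
    box = np.asarray(box)
    pts = [rng.uniform(0.25, 0.75, 3) * box]
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for _ in range(n_points - 1):
        d = d + 0.5 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(np.clip(pts[-1] + 2.5 * d, 0.1 * box, 0.9 * box))
    diam = rng.uniform(4.0, 10.0, n_points)
    return CenterlineSegment(np.asarray(pts), diam, organ)


@pytest.fixture(scope="session")
def obstructed_phantom():
    """One small obstructed phantom with exact truth (session-shared)."""
    cfg = PhantomConfig(
        grid=VolumeGrid((24, 24, 24), (6.0, 6.0, 6.0)),
        obstruction=Obstruction(transition_longitude=60.0, dilated_diameter_mm=40.0),
    )
    return generate_sample(cfg, seed=11)


@pytest.fixture(scope="session")
def plain_phantom():
    """One small unobstructed phantom (session-shared)."""
    cfg = PhantomConfig(grid=VolumeGrid((24, 24, 24), (6.0, 6.0, 6.0)))
    return generate_sample(cfg, seed=12)


@pytest.fixture()
def cylinder_annotations():
    """A straight 8 mm tube on a 1 mm isotropic grid, longitudes assigned."""
    grid = VolumeGrid((30, 20, 20), (1.0, 1.0, 1.0))
    seg = straight_segment(start=(5.0, 10.0, 10.0), length=20.0, diameter=8.0)
    return assign_longitudes(AnnotationSet([seg], grid))
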