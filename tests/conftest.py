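"""Shared fixtures: analytic shapes and small rendered corpora."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import nucleomorph as nm
from nucleomorph.contours import resample_closed


@pytest.fixture(scope="session")
def circle_spec() -> nm.SyntheticNucleusSpec:
    return nm.SyntheticNucleusSpec(semi_major=50.0, semi_minor=50.0)


@pytest.fixture(scope="session")
def ellipse_spec() -> nm.SyntheticNucleusSpec:
    return nm.SyntheticNucleusSpec(semi_major=30.0, semi_minor=20.0)


@pytest.fixture(scope="session")
def invaginated_spec() -> nm.SyntheticNucleusSpec:
    return nm.SyntheticNucleusSpec(
        semi_major=40.0,
        semi_minor=30.0,
        bumps=(nm.Bump(angle=1.0, width=0.3, amplitude=8.0, sign=-1),),
    )


@pytest.fixture(scope="session")
def circle_boundary(circle_spec) -> nm.NucleusBoundary:
    return nm.generate_boundary(circle_spec, 1000)


def bitten_disc(host_radius: float, bite_radii: tuple[float, ...]) -> np.ndarray:
    """Disc with circular bites centered on its boundary; 1000-point contour.

    Every concave point lies on a bite arc of known radius, so MNC and
    NC_max have closed-form expectations sqrt(a)/r_bite.
    """
    disc = Point(0, 0).buffer(host_radius, quad_segs=512)
    shape = disc
    # place bites on opposite sides so they never interact
    anchors = [(host_radius, 0), (-host_radius, 0), (0, host_radius)]
    for r_b, anchor in zip(bite_radii, anchors):
        shape = shape.difference(Point(*anchor).buffer(r_b, quad_segs=512))
    pts = np.array(shape.exterior.coords[:-1])
    return resample_closed(pts, 1000)


@pytest.fixture(scope="session")
def notched_square() -> np.ndarray:
    """100 px square with a semicircular notch r=20 in one edge (4000 points)."""
    square = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
    notch = Point(50, 100).buffer(20, quad_segs=256)
    pts = np.array(square.difference(notch).exterior.coords[:-1])
    return resample_closed(pts, 4000)


@pytest.fixture(scope="session")
def noise_free_corpus():
    """50+50 rendered frames without noise, with ground-truth boundaries."""
    return nm.generate_labeled_dataset(50, 50, seed=7, noise_model="none")


@pytest.fixture(scope="session")
def small_noisy_corpus():
    """10+10 rendered frames with the default noise model."""
    return nm.generate_labeled_dataset(10, 10, seed=11)


@pytest.fixture(scope="session")
def random_boundaries():
    """20 mixed-class analytic boundaries at 1000 points."""
    specs = nm.sample_nucleus_specs(10, 10, seed=5)
    return [nm.generate_boundary(s, 1000) for s in specs]
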