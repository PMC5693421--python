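"""Closed-contour primitives shared by the generator, segmenter and feature code.

A nucleus boundary is a closed polygonal curve stored as an ``(N, 2)`` float
array of sub-pixel ``(x, y)`` coordinates with *implicit* closure: the first
point is not repeated at the end.  The coordinate frame is the image frame,
``x`` = column, ``y`` = row, origin at the top-left pixel center.  Orientation
is normalized so the shoelace signed area is positive ("counter-clockwise" in
the (x, y) plane as stored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


class ContourError(ValueError):
    """Raised for degenerate or invalid closed contours."""


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of an implicitly closed polygon.

    Positive for counter-clockwise orientation in the stored (x, y) frame.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the contour with positive (counter-clockwise) orientation."""
    p = np.asarray(points, dtype=float)
    if signed_area(p) < 0:
        return p[::-1].copy()
    return p


def is_simple_polygon(points: np.ndarray) -> bool:
    """True if the implicitly closed polygon does not self-intersect."""
    return Polygon(np.asarray(points, dtype=float)).is_valid


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Edge lengths of the closed polygon, including the closing edge."""
    p = np.asarray(points, dtype=float)
    return np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)


def resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed contour to ``n_points`` arc-length-uniform vertices.

    Linear interpolation between existing vertices along cumulative arc
    length; the output keeps implicit closure (no duplicated endpoint) and
    starts at the original first vertex.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        raise ContourError("need at least 3 points to resample a closed contour")
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ContourError("contour has zero length")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


@dataclass
class NucleusBoundary:
    """Closed sub-pixel boundary of a single nucleus.

    ``points`` is an ``(N, 2)`` array of (x, y) coordinates, CCW, implicitly
    closed, arc-length-uniform (relative spacing deviation < 1% when produced
    by the segmentation or generator pipelines; N = 1000 by default there).
    """

    points: np.ndarray
    nucleus_id: int = 0
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.points = ensure_ccw(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ContourError("boundary points must be an (N, 2) array")
        if len(self.points) < 8:
            raise ContourError("boundary needs at least 8 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def resampled(self, n_points: int) -> "NucleusBoundary":
        return NucleusBoundary(
            resample_closed(self.points, n_points),
            nucleus_id=self.nucleus_id,
            source_image_id=self.source_image_id,
        )

    def transformed(
        self,
        scale: float = 1.0,
        rotation: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "NucleusBoundary":
        """Similarity transform (scale about origin, then rotate, then shift)."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        pts = (scale * self.points) @ rot.T + np.asarray(translation, dtype=float)
        return NucleusBoundary(
            pts, nucleus_id=self.nucleus_id, source_image_id=self.source_image_id
        )


def as_points(boundary) -> np.ndarray:
    """Accept a NucleusBoundary or raw (N, 2) array and return the array."""
    if isinstance(boundary, NucleusBoundary):
        return boundary.points
    return np.asarray(boundary, dtype=float)


def turn_signs(points: np.ndarray) -> np.ndarray:
    """Sign of the cross product of successive edge vectors at each vertex.

    Positive where the CCW polygon turns left (locally convex), negative at
    concave vertices.  Used as the dense-polygon concavity oracle.
    """
    p = ensure_ccw(np.asarray(points, dtype=float))
    e = np.roll(p, -1, axis=0) - p
    prev = np.roll(e, 1, axis=0)
    cross = prev[:, 0] * e[:, 1] - prev[:, 1] * e[:, 0]
    return np.sign(cross)
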