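"""Boundary-geometry features of a nucleus.

Three dimensionless dysmorphy features are computed from the closed boundary:

* **Relative concavity** ``RC = (h - a) / h`` where ``a`` is the enclosed
  (shoelace) area and ``h`` the area of the convex hull of the boundary
  points.  Zero for any convex shape.
* **Mean negative curvature** ``MNC = sqrt(a) * mean(|kappa_l|)`` over the
  boundary points whose signed curvature is negative (concave); defined as 0
  when the boundary has no concave points.
* **Maximum negative curvature** ``NC_max = sqrt(a) * max(|kappa_l|)`` over
  the same concave subset; 0 when there is none.

The signed curvature at boundary index ``l`` comes from the exact
circumcircle of the triple ``(l - w, l, l + w)`` with wrap-around indexing
and window ``w`` (25 points by default at N = 1000): ``kappa = 1/R`` with a
sign given by the orientation of the triple relative to the enforced CCW
boundary, so convex arcs have positive and concave arcs negative curvature.
Multiplying by ``sqrt(a)`` removes the pixel unit, so MNC and NC_max (like
the area ratio RC) transfer across magnifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .contours import ContourError, as_points, ensure_ccw, is_simple_polygon, signed_area

DEFAULT_CURVATURE_WINDOW = 25


@dataclass
class CurvatureProfile:
    """Signed extrinsic curvature (1/px) at every boundary point.

    ``kappa[l]`` is aligned with boundary point ``l``; ``window`` is the
    number of points to each side used in the circle fit.  For a perfect
    circle of radius r every entry equals 1/r to floating-point accuracy.
    """

    kappa: np.ndarray
    window: int


@dataclass
class ShapeFeatures:
    """Per-nucleus morphology descriptors (pixel units where dimensional)."""

    area_a: float
    hull_area_h: float
    rc: float
    mnc: float
    nc_max: float
    eccentricity: float
    orientation: float
    centroid: tuple[float, float]
    n_negative_points: int = 0

    @property
    def concavity_d(self) -> float:
        """Hull-minus-boundary area d = h - a (px^2)."""
        return self.hull_area_h - self.area_a

    def as_tuple(self) -> tuple[float, float, float]:
        """(rc, mnc, nc_max) in classifier order."""
        return (self.rc, self.mnc, self.nc_max)


def polygon_area(boundary) -> float:
    """Enclosed (shoelace) area of the closed boundary, px^2.

    Positive for the enforced CCW orientation; raises on self-intersecting
    input, for which the shoelace value is not an area.
    """
    pts = ensure_ccw(as_points(boundary))
    if not is_simple_polygon(pts):
        raise ContourError("boundary is self-intersecting; area undefined")
    return signed_area(pts)


def convex_hull_area(boundary) -> float:
    """Area of the convex hull of the boundary points, px^2."""
    pts = as_points(boundary)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ContourError("degenerate (collinear) boundary has no hull area") from exc
    return float(hull.volume)  # "volume" is area in 2D


def relative_concavity(boundary) -> float:
    """RC = (h - a)/h, dimensionless in [0, 1)."""
    a = polygon_area(boundary)
    h = convex_hull_area(boundary)
    if h <= 0:
        raise ContourError("degenerate boundary: zero hull area")
    # Hull of a point set can be a hair smaller than the shoelace area from
    # floating-point rounding on convex inputs; clamp at exactly 0.
    return max(0.0, (h - a) / h)


def boundary_curvature(boundary, window: int = DEFAULT_CURVATURE_WINDOW) -> CurvatureProfile:
    """Signed curvature by circumcircle fits over (l-w, l, l+w) triples.

    The circumcircle of three points has radius R = |e1||e2||e3| / (4 A)
    with A the triangle area, so the signed curvature is
    ``2 * cross(p2-p1, p3-p1) / (|e1||e2||e3|)`` — positive when the triple
    turns left (convex under CCW orientation).  Collinear triples get 0.
    """
    pts = ensure_ccw(as_points(boundary))
    n = len(pts)
    if n <= 2 * window:
        raise ContourError(
            f"boundary has {n} points but the curvature window needs more than "
            f"{2 * window}; resample the boundary or reduce the window"
        )
    p1 = np.roll(pts, window, axis=0)
    p2 = pts
    p3 = np.roll(pts, -window, axis=0)
    u = p2 - p1
    v = p3 - p1
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    d12 = np.linalg.norm(p2 - p1, axis=1)
    d23 = np.linalg.norm(p3 - p2, axis=1)
    d13 = np.linalg.norm(p3 - p1, axis=1)
    denom = d12 * d23 * d13
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return CurvatureProfile(kappa=kappa, window=window)


def mean_negative_curvature(boundary, profile: CurvatureProfile) -> float:
    """MNC = sqrt(a) * mean |kappa| over concave points; 0 when none."""
    pts = as_points(boundary)
    if len(profile.kappa) != len(pts):
        raise ValueError("curvature profile is not aligned with the boundary")
    neg = profile.kappa[profile.kappa < 0]
    if neg.size == 0:
        return 0.0
    a = polygon_area(pts)
    return float(np.sqrt(a) * np.mean(-neg))


def max_negative_curvature(boundary, profile: CurvatureProfile) -> float:
    """NC_max = sqrt(a) * largest |kappa| among concave points; 0 when none."""
    pts = as_points(boundary)
    if len(profile.kappa) != len(pts):
        raise ValueError("curvature profile is not aligned with the boundary")
    neg = profile.kappa[profile.kappa < 0]
    if neg.size == 0:
        return 0.0
    a = polygon_area(pts)
    return float(np.sqrt(a) * np.max(-neg))


def _polygon_moments(pts: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Area, centroid and central second moments of a closed polygon.

    Green's-theorem closed forms; returns (A, cx, cy, mu_xx, mu_yy, mu_xy)
    with mu the *normalized* central second moments (covariance of the
    uniform density over the enclosed region).
    """
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    c = x * yn - xn * y
    a = 0.5 * np.sum(c)
    if a <= 0:
        raise ContourError("degenerate boundary: zero enclosed area")
    cx = np.sum((x + xn) * c) / (6 * a)
    cy = np.sum((y + yn) * c) / (6 * a)
    sxx = np.sum((x * x + x * xn + xn * xn) * c) / 12.0
    syy = np.sum((y * y + y * yn + yn * yn) * c) / 12.0
    sxy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * c) / 24.0
    mu_xx = sxx / a - cx * cx
    mu_yy = syy / a - cy * cy
    mu_xy = sxy / a - cx * cy
    return float(a), float(cx), float(cy), float(mu_xx), float(mu_yy), float(mu_xy)


def eccentricity_orientation(boundary) -> tuple[float, float]:
    """Moment-equivalent-ellipse eccentricity and major-axis orientation.

    Eccentricity is sqrt(1 - (minor/major)^2) of the ellipse with the same
    normalized central second moments as the enclosed region; orientation is
    the major-axis angle in (-pi/2, pi/2], 0 by convention for a circle.
    """
    pts = ensure_ccw(as_points(boundary))
    _, _, _, mu_xx, mu_yy, mu_xy = _polygon_moments(pts)
    cov = np.array([[mu_xx, mu_xy], [mu_xy, mu_yy]])
    evals = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0:
        raise ContourError("degenerate boundary: zero second moments")
    ratio2 = max(0.0, min(1.0, lam_minor / lam_major))
    ecc = float(np.sqrt(1.0 - ratio2))
    if np.isclose(lam_minor, lam_major, rtol=1e-12, atol=1e-12 * lam_major):
        return ecc, 0.0
    theta = 0.5 * np.arctan2(2 * mu_xy, mu_xx - mu_yy)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return ecc, float(theta)


def compute_features(boundary, window: int = DEFAULT_CURVATURE_WINDOW) -> ShapeFeatures:
    """All per-nucleus features from one boundary."""
    pts = ensure_ccw(as_points(boundary))
    a = polygon_area(pts)
    h = convex_hull_area(pts)
    rc = max(0.0, (h - a) / h)
    profile = boundary_curvature(pts, window=window)
    neg = profile.kappa[profile.kappa < 0]
    sqrt_a = np.sqrt(a)
    mnc = float(sqrt_a * np.mean(-neg)) if neg.size else 0.0
    nc_max = float(sqrt_a * np.max(-neg)) if neg.size else 0.0
    ecc, theta = eccentricity_orientation(pts)
    _, cx, cy, *_ = _polygon_moments(pts)
    return ShapeFeatures(
        area_a=a,
        hull_area_h=h,
        rc=rc,
        mnc=mnc,
        nc_max=nc_max,
        eccentricity=ecc,
        orientation=theta,
        centroid=(cx, cy),
        n_negative_points=int(neg.size),
    )
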