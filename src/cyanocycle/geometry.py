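"""Contour geometry: volumes by rotational disk integration, equivalent-
ellipse shape summaries, and the daughter-axis-ratio prediction for
perpendicular, symmetric division.

Coccoid cells are ellipsoidal, not spherical.  A cell's volume is
reconstructed from its 2-D boundary contour by assuming rotational
symmetry about the major axis and summing circular disks whose radii are
the perpendicular distances from the axis to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional
import warnings

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Contour",
    "ShapeSummary",
    "contour_volume",
    "shape_summary",
    "predicted_daughter_ratio",
    "division_angle",
    "DivisionAngle",
    "ellipse_contour",
]

_AREA_TOL = 1e-9


@dataclass(frozen=True)
class Contour:
    """Closed polygon of cell-boundary points in physical coordinates [µm]."""

    points: np.ndarray  # (N, 2)
    frame_index: int = 0
    cell_id: Optional[int] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 (x, y) points")
        # drop an explicit closing vertex
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 distinct points")
        object.__setattr__(self, "points", pts)
        poly = Polygon(pts)
        if not poly.is_simple:
            raise ValueError("contour is self-intersecting")
        if poly.area < _AREA_TOL:
            raise ValueError("degenerate contour: vanishing area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)


class ShapeSummary(NamedTuple):
    """Equivalent-ellipse description of a contour."""

    major_axis_length: float  # full length [µm]
    minor_axis_length: float
    axis_ratio: float         # minor / major, in (0, 1]
    orientation: float        # major-axis angle, radians in [0, π)
    volume: float             # rotational volume [µm³]
    centroid: tuple


def _polygon_moments(pts: np.ndarray):
    """Area, centroid and second central area moments of a simple polygon
    (standard Green's-theorem edge sums; orientation-independent)."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = cross.sum() / 2.0
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    # second moments about the origin
    Ixx = ((y ** 2 + y * y1 + y1 ** 2) * cross).sum() / 12.0
    Iyy = ((x ** 2 + x * x1 + x1 ** 2) * cross).sum() / 12.0
    Ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    if A < 0:
        A, Ixx, Iyy, Ixy = -A, -Ixx, -Iyy, -Ixy
    # central moments
    Ixx -= A * cy ** 2
    Iyy -= A * cx ** 2
    Ixy -= A * cx * cy
    return A, (cx, cy), Ixx, Iyy, Ixy


def _principal_axes(pts: np.ndarray):
    """(centroid, unit major axis, unit minor axis, semi-axis lengths of the
    equivalent ellipse)."""
    A, (cx, cy), Ixx, Iyy, Ixy = _polygon_moments(pts)
    # normalized covariance of the enclosed region
    cov = np.array([[Iyy, Ixy], [Ixy, Ixx]]) / A
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending: evals[1] -> major axis
    a = 2.0 * np.sqrt(max(evals[1], 0.0))   # semi-major of equivalent ellipse
    b = 2.0 * np.sqrt(max(evals[0], 0.0))
    u_major = evecs[:, 1]
    u_minor = evecs[:, 0]
    return (cx, cy), u_major, u_minor, a, b


def contour_volume(contour: Contour, n_slices: int = 200) -> float:
    """Volume [µm³] by disk integration about the contour's major axis.

    The contour is sliced perpendicular to its principal (major) axis into
    ``n_slices`` equal-width bins; each slice contributes a circular disk
    π r² w whose radius is the mean of the absolute perpendicular
    distances of the boundary crossings above and below the axis.
    Rotational symmetry about the major axis is assumed.
    """
    if n_slices < 10:
        raise ValueError("n_slices must be >= 10")
    pts = contour.points
    (cx, cy), u, v, _, _ = _principal_axes(pts)
    rel = pts - np.array([cx, cy])
    s = rel @ u          # coordinate along the major axis
    d = rel @ v          # signed perpendicular distance

    s_lo, s_hi = s.min(), s.max()
    edges = np.linspace(s_lo, s_hi, n_slices + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = edges[1] - edges[0]

    # boundary crossings of each slicing line s = c with every polygon edge
    s2, d2 = np.roll(s, -1), np.roll(d, -1)
    ds = s2 - s
    vol = 0.0
    skipped = 0
    for c in centers:
        # edges straddling the line (half-open to count each crossing once)
        mask = ((s <= c) & (s2 > c)) | ((s2 <= c) & (s > c))
        if not mask.any():
            skipped += 1
            continue
        t = (c - s[mask]) / ds[mask]
        d_cross = d[mask] + t * (d2[mask] - d[mask])
        above = d_cross[d_cross > 0]
        below = d_cross[d_cross < 0]
        if len(above) == 0 or len(below) == 0:
            # grazing slice at the very tip: radius from whatever crossed
            r = np.abs(d_cross).mean()
        else:
            r = (above.mean() + np.abs(below).mean()) / 2.0
        vol += np.pi * r ** 2 * w
    if skipped:
        if skipped > 0.05 * n_slices:
            raise ValueError(f"{skipped}/{n_slices} slices found no boundary "
                             "crossing; contour too irregular")
        warnings.warn(f"{skipped} slices had no boundary crossing; skipped",
                      stacklevel=2)
    return float(vol)


def shape_summary(contour: Contour, n_slices: int = 200) -> ShapeSummary:
    """Axis lengths/orientation from the equivalent-ellipse second moments
    of the polygon, plus the rotational volume."""
    (cx, cy), u, _, a, b = _principal_axes(contour.points)
    if b <= 0 or a <= 0:
        raise ValueError("degenerate contour: zero axis length")
    theta = float(np.arctan2(u[1], u[0])) % np.pi
    return ShapeSummary(
        major_axis_length=2.0 * a,
        minor_axis_length=2.0 * b,
        axis_ratio=float(b / a),
        orientation=theta,
        volume=contour_volume(contour, n_slices=n_slices),
        centroid=(float(cx), float(cy)),
    )


def predicted_daughter_ratio(mother_ratio: float) -> float:
    """Axis ratio of daughters produced by symmetric division perpendicular
    to the mother's major axis.

    The daughter's major axis is the mother's minor axis; its minor axis is
    half the mother's major axis, so the daughter ratio is 0.5 / r (values
    above 1 are inverted to stay in (0, 1]).  A mother at the measured
    division ratio 0.63 yields daughters at 0.5/0.63 ≈ 0.79, matching the
    measured birth ratio and closing the eccentricity cycle.
    """
    if mother_ratio <= 0:
        raise ValueError("mother_ratio must be positive")
    if mother_ratio > 1:
        raise ValueError("axis ratio is minor/major and must be <= 1")
    r = 0.5 / mother_ratio
    return r if r <= 1.0 else 1.0 / r


class DivisionAngle(NamedTuple):
    degrees: float
    is_perpendicular: bool  # acute angle > 60°
    defined: bool


def division_angle(mother: ShapeSummary, daughter: ShapeSummary,
                   ratio_tol: float = 1e-9) -> DivisionAngle:
    """Acute angle between the mother's and daughter's major axes, with a
    perpendicularity flag (> 60°).  Undefined when either shape is a
    circle (axis ratio 1), whose orientation is arbitrary."""
    if (1.0 - mother.axis_ratio) < ratio_tol or (1.0 - daughter.axis_ratio) < ratio_tol:
        return DivisionAngle(float("nan"), False, False)
    diff = abs(mother.orientation - daughter.orientation) % np.pi
    ang = min(diff, np.pi - diff)
    deg = float(np.degrees(ang))
    return DivisionAngle(deg, deg > 60.0, True)


def ellipse_contour(center=(0.0, 0.0), semi_major: float = 1.0,
                    semi_minor: float = 1.0, orientation: float = 0.0,
                    n_points: int = 64, frame_index: int = 0,
                    cell_id: Optional[int] = None) -> Contour:
    """Analytic ellipse boundary sampled at ``n_points`` vertices —
    the standard synthetic contour used throughout tests and rendering."""
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    x = semi_major * np.cos(t)
    y = semi_minor * np.sin(t)
    c, s = np.cos(orientation), np.sin(orientation)
    pts = np.column_stack([center[0] + c * x - s * y,
                           center[1] + s * x + c * y])
    return Contour(points=pts, frame_index=frame_index, cell_id=cell_id)
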