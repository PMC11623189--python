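"""Pen geometry: the feed-surface boundary curve and trough-zone classification.

The feed trough is covered by an image-space polygon (the trough-rail
range). Inside it, a polynomial fitted to manually marked highest-feed
points separates two head positions: a mouth at or below the feed surface
(feeding) and a mouth inside the rail but above the surface (picking).
Image coordinates follow the raster convention — origin top-left, y
increasing downward — so "below the feed surface" means ``y >= curve(x)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon


class GeometryError(ValueError):
    """Raised for invalid geometry inputs (too few points, degenerate fits)."""


class Zone(Enum):
    """Partition of the image plane relative to the trough."""

    OUTSIDE = "outside"
    PICKING_ZONE = "picking_zone"
    FEEDING_ZONE = "feeding_zone"


@dataclass(frozen=True)
class FeedPoint:
    """A marked highest-feed point in pixel coordinates (y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GeometryError("feed point coordinates must be finite")
        if self.x < 0 or self.y < 0:
            raise GeometryError("feed point coordinates must be non-negative")


@dataclass
class BoundaryCurve:
    """Least-squares polynomial through the marked feed points.

    Attributes
    ----------
    coefficients : ndarray
        Polynomial coefficients, highest degree first (numpy convention).
    degree : int
        Degree of the fitted polynomial.
    domain : tuple of float
        ``(x_min, x_max)`` span of the fit points. Evaluation outside the
        domain extrapolates; it is logged with a warning, not fatal.
    rss : float
        Residual sum of squares of the vertical residuals.
    """

    coefficients: np.ndarray
    degree: int
    domain: tuple[float, float]
    rss: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.degree + 1:
            raise GeometryError("coefficient count must equal degree + 1")
        if not self.domain[0] < self.domain[1]:
            raise GeometryError("curve domain must satisfy x_min < x_max")
        if self.rss < 0:
            raise GeometryError("rss must be non-negative")

    def __call__(self, x):
        """Evaluate the curve; extrapolation outside the domain warns."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.domain[0]) or np.any(x > self.domain[1]):
            warnings.warn(
                "boundary curve evaluated outside its fitted domain "
                f"[{self.domain[0]:g}, {self.domain[1]:g}] (extrapolating)",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.polyval(self.coefficients, x)


@dataclass
class TroughRegion:
    """Simple polygon (>= 3 vertices, positive area) covering the trough."""

    vertices: Sequence[tuple[float, float]]
    _polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError("trough polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise GeometryError("trough polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise GeometryError("trough polygon must have positive area")
        self._polygon = poly

    def contains(self, x: float, y: float) -> bool:
        """Point-in-region test; the polygon boundary is inclusive."""
        return bool(self._polygon.covers(Point(x, y)))


def fit_boundary(points: Sequence[FeedPoint], degree: int = 3) -> BoundaryCurve:
    """Fit the feed-surface boundary polynomial by least squares.

    Parameters
    ----------
    points : sequence of FeedPoint
        Marked highest-feed points; at least ``degree + 1`` required.
    degree : int
        Polynomial degree (>= 1). Default 3: the trough line under a
        downward-looking camera is gently curved by perspective.

    Returns
    -------
    BoundaryCurve
        Fitted curve with its residual sum of squares and x-domain.

    Raises
    ------
    GeometryError
        If there are fewer than ``degree + 1`` points ("insufficient
        points") or the design matrix is rank-deficient, e.g. duplicate
        x values ("degenerate fit").
    """
    if degree < 1:
        raise GeometryError("degree must be >= 1")
    if len(points) < degree + 1:
        raise GeometryError(
            f"insufficient points: need at least {degree + 1} for degree {degree}, "
            f"got {len(points)}"
        )
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise GeometryError("degenerate fit: all x values identical")

    vander = np.vander(x, degree + 1)
    if np.linalg.matrix_rank(vander) < degree + 1:
        raise GeometryError("degenerate fit: rank-deficient design matrix")
    coeffs, _, _, _ = np.linalg.lstsq(vander, y, rcond=None)
    rss = float(np.sum((vander @ coeffs - y) ** 2))
    return BoundaryCurve(
        coefficients=coeffs,
        degree=degree,
        domain=(float(x.min()), float(x.max())),
        rss=rss,
    )


def classify_zone(
    point: tuple[float, float], curve: BoundaryCurve, region: TroughRegion
) -> Zone:
    """Classify an image point into OUTSIDE / PICKING_ZONE / FEEDING_ZONE.

    A point outside the trough polygon is OUTSIDE regardless of the curve.
    Inside, ``y >= curve(x)`` (at or below the feed surface, y down) is
    FEEDING_ZONE; strictly above it is PICKING_ZONE. A point exactly on
    the curve counts as feeding: the behavioral trigger is mouth-feed
    contact.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise GeometryError("point coordinates must be finite")
    if not region.contains(x, y):
        return Zone.OUTSIDE
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        y_curve = float(curve(x))
    return Zone.FEEDING_ZONE if y >= y_curve else Zone.PICKING_ZONE
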