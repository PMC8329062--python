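"""Planar closed-contour primitives.

All coordinates are physical millimetres.  The image convention is 0-based
pixel indices, x rightward, y downward, with a pixel's centre at
``(index + 0.5) * pixel_spacing``.  "Counterclockwise" throughout means
positive shoelace (signed) area in these coordinates.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Base class for contour geometry failures."""


class SelfIntersectionError(GeometryError):
    """The polygon boundary crosses itself."""


class TopologyError(GeometryError):
    """A mask is not a single, hole-free connected component."""


class OutOfBoundsError(GeometryError):
    """A contour does not fit inside the raster grid."""


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = CCW)."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*((np.roll(points, -1, axis=0) - points).T))))


def is_simple(points: np.ndarray) -> bool:
    """True when the closed polygon does not self-intersect."""
    poly = Polygon(points)
    return poly.is_valid and poly.area > 0


def canonical_start_index(points: np.ndarray) -> int:
    """Index of the lexicographically smallest vertex (min x, ties by min y).

    In the canonical right-side frame this is the medially most extreme
    boundary point, which anchors the arc-length correspondence.
    """
    return int(np.lexsort((points[:, 1], points[:, 0]))[0])


def _roll_to_start(points: np.ndarray) -> np.ndarray:
    return np.roll(points, -canonical_start_index(points), axis=0)


def canonicalize(points: np.ndarray) -> np.ndarray:
    """Enforce CCW orientation and the min-x/min-y start rule."""
    if signed_area(points) < 0:
        points = points[::-1]
    return _roll_to_start(points)


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` vertices equally spaced by arc length.

    The first input vertex is kept as the starting point.
    """
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate contour with zero perimeter")
    target = np.arange(n) * (total / n)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


class Contour:
    """Ordered closed CCW point sequence with arc-length correspondence.

    Parameters
    ----------
    points : (K, 2) array of mm coordinates.  Must be finite, simple
        (non-self-intersecting), counterclockwise, with no two consecutive
        vertices identical.
    """

    __slots__ = ("points",)

    def __init__(self, points, validate: bool = True):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError(f"contour needs a (K>=3, 2) array, got {pts.shape}")
        if validate:
            if not np.all(np.isfinite(pts)):
                raise GeometryError("contour contains non-finite coordinates")
            seg = np.hypot(*((np.roll(pts, -1, axis=0) - pts).T))
            if np.min(seg) <= 0:
                raise GeometryError("two consecutive contour points coincide")
            if signed_area(pts) <= 0:
                raise GeometryError("contour must be counterclockwise (positive area)")
            if not is_simple(pts):
                raise SelfIntersectionError("contour is self-intersecting")
        self.points = pts

    # -- basic measures ----------------------------------------------------
    @property
    def K(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return signed_area(self.points)

    @property
    def perimeter(self) -> float:
        return perimeter(self.points)

    @property
    def centroid(self) -> np.ndarray:
        """Vertex centroid (equals the curve centroid for arc-length sampling)."""
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Root mean squared vertex distance to the centroid."""
        d = self.points - self.centroid
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    # -- transforms --------------------------------------------------------
    def canonical(self) -> "Contour":
        return Contour(canonicalize(self.points), validate=False)

    def resample(self, n: int) -> "Contour":
        return Contour(resample_closed(self.points, n), validate=False)

    def mirrored(self, axis_x: float, restart: bool = True) -> "Contour":
        """Reflect about the vertical line ``x = axis_x``.

        With ``restart=True`` (the left-to-canonical-frame mapping) the
        orientation is re-normalized to CCW and the min-x start rule is
        re-applied, so landmark 0 remains the medially most extreme point.
        With ``restart=False`` the reflection preserves landmark labels
        (vertex 0 stays vertex 0, order reversed to restore CCW); this is the
        form under which mirror-closed shape sets are exactly closed, used
        for symmetric template construction.
        """
        q = self.points.copy()
        q[:, 0] = 2.0 * axis_x - q[:, 0]
        if restart:
            q = q[::-1]
            q = _roll_to_start(q)
        else:
            q = np.roll(q[::-1], 1, axis=0)  # reverse but keep vertex 0 first
        return Contour(q, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Contour(K={self.K}, area={self.area:.2f} mm^2)"


def points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorised over points.

    A point exactly on an edge may fall on either side; callers place query
    points at pixel centres away from grid-aligned edges.
    """
    x = poly[:, 0]
    y = poly[:, 1]
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for k in range(len(x)):
        if y[k] == y2[k]:
            continue
        cond = (y[k] > py) != (y2[k] > py)
        if not np.any(cond):
            continue
        xi = x[k] + (py[cond] - y[k]) * (x2[k] - x[k]) / (y2[k] - y[k])
        hit = np.zeros(px.shape, dtype=bool)
        hit[cond] = px[cond] < xi
        inside ^= hit
    return inside


def rasterize_polygon(
    contour: Contour, grid: tuple[int, int], pixel_spacing: float
) -> np.ndarray:
    """Binary raster of a contour: pixel set iff its centre is inside (even-odd).

    ``grid`` is (H, W) in pixels; pixel centres sit at (index + 0.5) * spacing.
    """
    H, W = grid
    s = float(pixel_spacing)
    pts = contour.points
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > W * s
        or pts[:, 1].max() > H * s
    ):
        raise OutOfBoundsError(
            f"contour bbox x[{pts[:, 0].min():.2f},{pts[:, 0].max():.2f}] "
            f"y[{pts[:, 1].min():.2f},{pts[:, 1].max():.2f}] mm exceeds "
            f"grid {W * s:.1f}x{H * s:.1f} mm"
        )
    j0 = max(int(np.floor(pts[:, 0].min() / s - 0.5)), 0)
    j1 = min(int(np.ceil(pts[:, 0].max() / s + 0.5)), W)
    i0 = max(int(np.floor(pts[:, 1].min() / s - 0.5)), 0)
    i1 = min(int(np.ceil(pts[:, 1].max() / s + 0.5)), H)
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    cx = (jj.ravel() + 0.5) * s
    cy = (ii.ravel() + 0.5) * s
    inside = points_in_polygon(cx, cy, pts).reshape(ii.shape)
    out = np.zeros((H, W), dtype=bool)
    out[i0:i1, j0:j1] = inside
    return out
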