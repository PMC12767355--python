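"""Small geometric primitives shared across modules.

Conventions used throughout the package:

* Coordinates are in micrometers (um) with the x axis along the
  mediolateral (ML) axis by default and the y axis along the
  anterior-posterior (AP) axis.
* Pixel (row i, col j) of an image has its center at
  ``((j + 0.5) * px, (i + 0.5) * px)`` um; pixel *corners* (where four
  pixels meet) sit at integer multiples of the pixel size.
* Regions are axis-aligned half-open boxes: a point belongs to a region
  iff ``origin <= p < origin + size`` in both coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned analysis region (e.g. a 50x50 um box).

    ``origin_um`` is the (x, y) corner; inclusion of boundary objects
    follows the half-open convention [origin, origin + size).
    """

    origin_um: tuple[float, float]
    size_um: tuple[float, float]

    def __post_init__(self):
        if min(self.size_um) <= 0:
            raise ValueError("region size must be positive")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized half-open containment test for (n, 2) points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ox, oy = self.origin_um
        sx, sy = self.size_um
        return (
            (xy[:, 0] >= ox)
            & (xy[:, 0] < ox + sx)
            & (xy[:, 1] >= oy)
            & (xy[:, 1] < oy + sy)
        )

    @property
    def area_um2(self) -> float:
        return float(self.size_um[0] * self.size_um[1])


def fold_angle_deg(dx: float | np.ndarray, dy: float | np.ndarray) -> np.ndarray:
    """Angle of a direction relative to the x (ML) axis, folded into [0, 90].

    An undirected line segment has no sign or orientation, so 135 deg
    raw folds to 45 deg and the result is invariant to reversing the
    segment.
    """
    ang = np.degrees(np.arctan2(np.abs(np.asarray(dy, dtype=float)),
                                np.abs(np.asarray(dx, dtype=float))))
    return ang


def chord_angle_deg(polyline_um: np.ndarray, ml_axis: str = "x") -> float:
    """Folded angle of the end-to-end chord of a polyline vs the ML axis."""
    p = np.asarray(polyline_um, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    d = p[-1] - p[0]
    if np.hypot(*d) == 0:
        raise ValueError("zero-length chord: angle undefined")
    if ml_axis == "x":
        return float(fold_angle_deg(d[0], d[1]))
    elif ml_axis == "y":
        return float(fold_angle_deg(d[1], d[0]))
    raise ValueError(f"ml_axis must be 'x' or 'y', got {ml_axis!r}")


def polyline_length(polyline_um: np.ndarray) -> float:
    """Arc length of a polyline (sum of segment lengths)."""
    p = np.asarray(polyline_um, dtype=float)
    if p.shape[0] < 2:
        return 0.0
    return float(np.sum(np.hypot(*(np.diff(p, axis=0).T))))


def point_at_arc_fraction(polyline_um: np.ndarray, fraction: float) -> np.ndarray:
    """Point at a given arc-length fraction along a polyline."""
    p = np.asarray(polyline_um, dtype=float)
    seg = np.hypot(*(np.diff(p, axis=0).T))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return p[0].copy()
    target = np.clip(fraction, 0.0, 1.0) * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return p[i] + t * (p[i + 1] - p[i])


def point_to_polyline_distance(point_um: np.ndarray, polyline_um: np.ndarray) -> float:
    """Minimum distance from a point to a polyline (segment-wise)."""
    q = np.asarray(point_um, dtype=float)
    p = np.asarray(polyline_um, dtype=float)
    if p.shape[0] == 1:
        return float(np.hypot(*(q - p[0])))
    a, b = p[:-1], p[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", q - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.hypot(*(q - proj).T)))


def disk_pixel_indices(center_um, radius_um, pixel_size_um, shape):
    """Row/col indices of pixels whose centers fall within a disk.

    Returns ``(rows, cols)`` clipped to the image bounds.
    """
    cx, cy = float(center_um[0]), float(center_um[1])
    px = pixel_size_um
    r = radius_um
    i0 = max(int(np.floor((cy - r) / px - 0.5)), 0)
    i1 = min(int(np.ceil((cy + r) / px - 0.5)) + 1, shape[0])
    j0 = max(int(np.floor((cx - r) / px - 0.5)), 0)
    j1 = min(int(np.ceil((cx + r) / px - 0.5)) + 1, shape[1])
    if i0 >= i1 or j0 >= j1:
        return np.empty(0, int), np.empty(0, int)
    ii, jj = np.mgrid[i0:i1, j0:j1]
    yc = (ii + 0.5) * px
    xc = (jj + 0.5) * px
    keep = (xc - cx) ** 2 + (yc - cy) ** 2 <= r * r
    return ii[keep], jj[keep]


# ---------------------------------------------------------------------------
# Smallest enclosing circle (Welzl) on points; used for merging gap ROIs.
# ---------------------------------------------------------------------------

def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.hypot(*(a - b)) / 2.0)


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(p, center, radius, eps=1e-9):
    return np.hypot(*(p - center)) <= radius + eps


def smallest_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Welzl's algorithm (iterative, shuffled deterministically)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] == 0:
        raise ValueError("no points")
    order = np.random.default_rng(0).permutation(pts.shape[0])
    pts = pts[order]
    center, radius = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        if _in_circle(pts[i], center, radius):
            continue
        center, radius = pts[i].copy(), 0.0
        for j in range(i):
            if _in_circle(pts[j], center, radius):
                continue
            center, radius = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], center, radius):
                    continue
                res = _circle_three(pts[i], pts[j], pts[k])
                if res is not None:
                    center, radius = res
    return center, radius


def enclosing_circle_of_circles(centers: np.ndarray, radii: np.ndarray,
                                n_boundary: int = 128) -> tuple[np.ndarray, float]:
    """Minimum circle containing a set of circles.

    Exact for one or two circles; for more, Welzl on densely sampled
    boundary points (relative error < 0.1% at the default sampling).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if len(radii) == 1:
        return centers[0].copy(), float(radii[0])
    if len(radii) == 2:
        (c1, c2), (r1, r2) = centers, radii
        d = float(np.hypot(*(c2 - c1)))
        if d + r2 <= r1:
            return c1.copy(), float(r1)
        if d + r1 <= r2:
            return c2.copy(), float(r2)
        r = (d + r1 + r2) / 2.0
        u = (c2 - c1) / d
        center = c1 + (r - r1) * u
        return center, float(r)
    theta = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    pts = (centers[:, None, :] + radii[:, None, None] * ring[None, :, :]).reshape(-1, 2)
    center, radius = smallest_enclosing_circle(pts)
    # inflate minimally so every circle is truly contained despite sampling
    need = np.max(np.hypot(*(centers - center).T) + radii)
    return center, float(max(radius, need))
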