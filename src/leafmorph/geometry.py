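"""Planar polygon primitives shared by the morphometry and synthesis code.

All outlines are simple planar polygons in millimetres. Vertices are
``(n, 2)`` float arrays, implicitly closed (last vertex joins the first).
Areas come from the shoelace formula, perimeters from polyline arc length,
and orientation from the principal axes of the area moment tensor, so every
measurement is rotation- and translation-invariant.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from .errors import ExtrapolationError, GeometryError

__all__ = [
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "polygon_inertia",
    "principal_angle",
    "rotate",
    "ensure_ccw",
    "check_simple",
    "circularity",
    "superellipse_lobe",
    "arc_through",
    "arc_from_tangent",
    "biarc",
    "signed_angle",
]

_SIMPLE_TOL = 1e-9  # mm; segment-sweep tolerance for self-intersection tests


def _as_vertices(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError("vertices must be an (n>=3, 2) array")
    return v


def polygon_area(vertices) -> float:
    """Signed shoelace area (positive for counter-clockwise polygons)."""
    v = _as_vertices(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(vertices, closed: bool = True) -> float:
    """Arc length of the polyline; include the closing edge if ``closed``."""
    v = np.asarray(vertices, dtype=float)
    d = np.diff(v, axis=0)
    length = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed:
        length += float(np.hypot(*(v[0] - v[-1])))
    return length


def polygon_centroid(vertices) -> np.ndarray:
    v = _as_vertices(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        raise GeometryError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_inertia(vertices) -> np.ndarray:
    """Central second area moment tensor [[Ixx, Ixy], [Ixy, Iyy]].

    Ixx here is the second moment of the x-coordinate (variance-like), so the
    eigenvector of the largest eigenvalue is the long (principal) axis.
    """
    v = _as_vertices(vertices) - polygon_centroid(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    # standard polygon second-moment integrals about the centroid
    ixx = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
    iyy = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
    ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    a = 0.5 * cross.sum()
    sign = 1.0 if a > 0 else -1.0
    return sign * np.array([[ixx, ixy], [ixy, iyy]])


def principal_angle(vertices) -> float:
    """Angle (radians) of the long principal axis of the area distribution."""
    inertia = polygon_inertia(vertices)
    evals, evecs = np.linalg.eigh(inertia)
    major = evecs[:, int(np.argmax(evals))]
    return float(np.arctan2(major[1], major[0]))


def rotate(points, angle: float, about=None) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    if about is None:
        return p @ rot.T
    about = np.asarray(about, dtype=float)
    return (p - about) @ rot.T + about


def ensure_ccw(vertices) -> np.ndarray:
    v = _as_vertices(vertices)
    return v if polygon_area(v) > 0 else v[::-1].copy()


def check_simple(vertices) -> None:
    """Raise GeometryError if the closed polygon self-intersects."""
    v = _as_vertices(vertices)
    poly = Polygon(v)
    if not poly.is_valid or poly.area <= _SIMPLE_TOL**2:
        raise GeometryError("polygon is self-intersecting or degenerate")


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric ratio 4*pi*A/P**2; 1 for a disk, < 1 otherwise."""
    if perimeter <= 0:
        raise GeometryError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def superellipse_lobe(length: float, height: float, exponent: float,
                      n: int = 257) -> np.ndarray:
    """Open superellipse half-lobe from (0, 0) to (length, 0), apex at
    (length/2, height): points of |2x/L - 1|^p + (y/h)^p = 1 with y >= 0.

    The parametrisation guarantees a vertex exactly at the apex (odd point
    counts), so mid-transect widths measured on the polygon are exact.
    """
    if length <= 0 or height <= 0 or exponent <= 0:
        raise GeometryError("length, height and exponent must be positive")
    if n % 2 == 0:
        n += 1
    t = np.linspace(np.pi, 0.0, n)  # x increasing
    ct, st = np.cos(t), np.sin(t)
    x = length / 2.0 * (1.0 + np.sign(ct) * np.abs(ct) ** (2.0 / exponent))
    y = height * np.abs(st) ** (2.0 / exponent)
    x[0], y[0] = 0.0, 0.0
    x[-1], y[-1] = length, 0.0
    return np.column_stack([x, y])


def signed_angle(a, b) -> float:
    """Signed angle (radians, in (-pi, pi]) rotating vector a onto vector b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b))


def arc_through(p1, p2, alpha: float, n: int = 64) -> np.ndarray:
    """Circular arc from p1 to p2 with signed tangent-chord angle ``alpha``.

    ``alpha`` is the angle from the chord direction (p2 - p1) to the arc's
    tangent at p1; by the inscribed-angle theorem the arc subtends a central
    angle of 2*alpha. alpha > 0 bulges to the left of the chord. alpha = 0
    degenerates to the straight chord. Returns n points including endpoints.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    chord = p2 - p1
    c = float(np.hypot(*chord))
    if c < _SIMPLE_TOL:
        raise ExtrapolationError("arc endpoints coincide")
    if abs(alpha) >= np.pi:
        raise ExtrapolationError("tangent-chord angle must be below 180 deg")
    if abs(alpha) < 1e-9:
        t = np.linspace(0.0, 1.0, n)[:, None]
        return p1 + t * chord
    radius = c / (2.0 * np.sin(abs(alpha)))
    mid = 0.5 * (p1 + p2)
    # unit normal to the left of the chord
    left = np.array([-chord[1], chord[0]]) / c
    # centre sits opposite the bulge side
    h = np.sqrt(max(radius**2 - (c / 2.0) ** 2, 0.0))
    centre = mid - np.sign(alpha) * h * left
    a1 = np.arctan2(*(p1 - centre)[::-1])
    # a left bulge (alpha > 0) is traversed clockwise around its centre
    sweep = -2.0 * alpha
    angles = a1 + np.linspace(0.0, sweep, n)
    pts = centre + radius * np.column_stack([np.cos(angles), np.sin(angles)])
    pts[0], pts[-1] = p1, p2
    return pts


def arc_from_tangent(p, tangent, q, n: int = 64) -> np.ndarray:
    """Arc from p to q whose tangent at p equals ``tangent`` exactly."""
    alpha = signed_angle(np.asarray(q, float) - np.asarray(p, float), tangent)
    return arc_through(p, q, alpha, n=n)


def biarc(p1, t1, p2, t2, n: int = 64) -> np.ndarray:
    """Two tangent-continuous arcs joining (p1, t1) to (p2, t2) exactly.

    Uses the classic equal-parameter construction: the junction lies at
    J = (p1 + d*t1 + p2 - d*t2) / 2 with d solving the tangency quadratic.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    t1 = np.asarray(t1, dtype=float) / np.hypot(*t1)
    t2 = np.asarray(t2, dtype=float) / np.hypot(*t2)
    v = p2 - p1
    dot = float(t1 @ t2)
    b = float(v @ (t1 + t2))
    vv = float(v @ v)
    if vv < _SIMPLE_TOL**2:
        raise ExtrapolationError("biarc endpoints coincide")
    if abs(1.0 - dot) < 1e-12:  # parallel tangents
        if abs(b) < 1e-12:
            raise ExtrapolationError("biarc infeasible: antiparallel geometry")
        d = vv / (2.0 * b)
    else:
        disc = b * b + 2.0 * (1.0 - dot) * vv
        d = (-b + np.sqrt(disc)) / (2.0 * (1.0 - dot))
    junction = 0.5 * (p1 + d * t1 + p2 - d * t2)
    half = max(n // 2, 4)
    first = arc_from_tangent(p1, t1, junction, n=half)
    # second arc: arrive at p2 with tangent t2 <=> leave p2 backwards with -t2
    second = arc_from_tangent(p2, -t2, junction, n=half)[::-1]
    return np.vstack([first, second[1:]])
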