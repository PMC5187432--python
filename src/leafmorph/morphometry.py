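"""Tegmen morphometrics: ten raw measurements, four dimension-free shape
descriptors, the leaf-like binary coding, and completion of incomplete
(fossil) outlines.

The forewing (tegmen) is treated as a simple planar polygon split by the
radius vein polyline into an anterior and a posterior field. From an outline
we take ten raw measurements (maximal length; width on the middle; anterior
and posterior field widths; total, anterior and posterior areas; total,
anterior and posterior perimeters) and reduce them to four dimension-free
descriptors:

* ``ratio_wl``            — width / length,
* ``ratio_field_width``   — anterior field width / posterior field width,
* ``ratio_field_area``    — anterior field area / posterior field area,
* ``circularity_anterior``— 4*pi*(anterior area)/(anterior perimeter)**2.

Measurement conventions (all documented in the methods note): outlines are
orientation-normalised by the principal axis of the area moments before
measurement; all widths are taken on the transect perpendicular to the
principal axis at 50% of the maximal length; mirror-image outlines yield
identical records.

Incomplete outlines (apex missing, as in the fossil) are measured twice:
once on the clipped polygon closed by the straight cut chord, and once after
completing the apex with a circular arc whose tangents best match the open
endpoints (a tangent-continuous biarc when the single-arc mismatch exceeds
30 degrees).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split

from . import geometry as geom
from .errors import (
    DataError,
    ExtrapolationError,
    GeometryError,
    TopologyError,
)

__all__ = [
    "WingMeasurementRecord",
    "ShapeParameters",
    "WingOutline",
    "LeafLike",
    "DESCRIPTOR_NAMES",
    "measure_outline",
    "compute_parameters",
    "code_leaf_like",
    "extrapolate_tip",
]

#: canonical descriptor column names, in pipeline order
DESCRIPTOR_NAMES = (
    "ratio_wl",
    "ratio_field_width",
    "ratio_field_area",
    "circularity_anterior",
)

_AREA_PARTITION_EPS = 1e-6
_WIDTH_SUM_RTOL = 0.05  # field widths vs mid width, same transect
_BIARC_MISMATCH_DEG = 30.0


@dataclass
class WingMeasurementRecord:
    """One taxon's ten raw tegmen measurements (mm, mm^2) plus labels."""

    taxon_id: str
    length_max: float
    width_mid: float
    width_anterior_field: float
    width_posterior_field: float
    area_total: float
    area_anterior: float
    area_posterior: float
    perimeter_total: float
    perimeter_anterior: float
    perimeter_posterior: float
    subfamily: Optional[str] = None
    thorax_height: Optional[float] = None

    _MEASUREMENTS = (
        "length_max", "width_mid", "width_anterior_field",
        "width_posterior_field", "area_total", "area_anterior",
        "area_posterior", "perimeter_total", "perimeter_anterior",
        "perimeter_posterior",
    )

    def validate(self) -> "WingMeasurementRecord":
        for name in self._MEASUREMENTS:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise DataError(
                    f"measurement '{name}' must be positive and finite, "
                    f"got {value!r} (taxon {self.taxon_id})")
        if (self.area_anterior + self.area_posterior
                > self.area_total * (1.0 + _AREA_PARTITION_EPS)):
            raise DataError(
                f"anterior + posterior areas exceed total area "
                f"(taxon {self.taxon_id})")
        width_sum = self.width_anterior_field + self.width_posterior_field
        if abs(width_sum - self.width_mid) > _WIDTH_SUM_RTOL * self.width_mid:
            raise DataError(
                f"field widths must sum to the mid width within "
                f"{_WIDTH_SUM_RTOL:.0%} (taxon {self.taxon_id}): "
                f"{width_sum:.4g} vs {self.width_mid:.4g}")
        return self


@dataclass
class ShapeParameters:
    """The four dimension-free shape descriptors (+ optional binary)."""

    ratio_wl: float
    ratio_field_width: float
    ratio_field_area: float
    circularity_anterior: float
    leaf_like: Optional[bool] = None

    def validate(self) -> "ShapeParameters":
        for name in DESCRIPTOR_NAMES:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise DataError(f"descriptor '{name}' must be positive, "
                                f"got {value!r}")
        if self.circularity_anterior > 1.0 + 1e-9:
            raise DataError("circularity_anterior exceeds the isoperimetric "
                            f"bound 1: {self.circularity_anterior!r}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES])


class LeafLike(enum.Enum):
    """Binary leaf-like coding; UNKNOWN when the thorax is not preserved."""

    LEAF_LIKE = "leaf_like"
    NOT_LEAF_LIKE = "not_leaf_like"
    UNKNOWN = "unknown"


@dataclass
class WingOutline:
    """Digitised tegmen outline: closed vertex chain + radius split line.

    ``vertices`` is implicitly closed when ``completeness == "complete"``;
    for a tip-missing outline it is an open chain whose first and last
    points are the cut endpoints. ``end_tangents`` holds the boundary's
    unit travel directions in chain orientation: the direction with which
    the (missing) boundary arrives at the first point, and the direction
    with which it leaves the last point into the gap.
    """

    vertices: np.ndarray
    split_polyline: Optional[np.ndarray] = None
    completeness: str = "complete"  # or "tip_missing"
    open_endpoints: Optional[np.ndarray] = None  # (2, 2): start, end
    end_tangents: Optional[np.ndarray] = None    # (2, 2): at start, at end
    taxon_id: str = "outline"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.split_polyline is not None:
            self.split_polyline = np.asarray(self.split_polyline, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("outline vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 8:
            raise GeometryError("outline needs at least 8 vertices")
        if self.completeness not in ("complete", "tip_missing"):
            raise GeometryError(
                f"unknown completeness flag {self.completeness!r}")

    @property
    def diameter(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.hypot(*(hi - lo)))


# ---------------------------------------------------------------------------
# measurement


def _orientation_normalize(outline: WingOutline) -> WingOutline:
    """Rotate so the principal (long) axis lies along +x.

    Mirror images produce identical measurements because every downstream
    quantity (extents, face areas, perimeters) is reflection-invariant.
    """
    angle = geom.principal_angle(outline.vertices)
    verts = geom.rotate(outline.vertices, -angle)
    split = (geom.rotate(outline.split_polyline, -angle)
             if outline.split_polyline is not None else None)
    pts = (geom.rotate(outline.open_endpoints, -angle)
           if outline.open_endpoints is not None else None)
    tans = (geom.rotate(outline.end_tangents, -angle)
            if outline.end_tangents is not None else None)
    return replace(outline, vertices=verts, split_polyline=split,
                   open_endpoints=pts, end_tangents=tans)


def _extended_splitter(split: np.ndarray, scale: float) -> LineString:
    """Extend the radius polyline past both ends so it fully crosses."""
    first = split[0] + (split[0] - split[1]) / np.hypot(*(split[0] - split[1])) * 0.05 * scale
    last = split[-1] + (split[-1] - split[-2]) / np.hypot(*(split[-1] - split[-2])) * 0.05 * scale
    return LineString(np.vstack([first, split, last]))


def _split_fields(poly: Polygon, split: np.ndarray, scale: float):
    """Split the outline polygon by the radius; return (anterior, posterior).

    The anterior field is the face lying to the left of the directed split
    polyline (first point -> last point).
    """
    for endpoint in (split[0], split[-1]):
        if poly.exterior.distance(Point(endpoint)) > max(1e-6, 1e-9 * scale):
            raise TopologyError(
                "split polyline endpoints must lie on the outline")
    pieces = shapely_split(poly, _extended_splitter(split, scale))
    faces = [g for g in pieces.geoms if isinstance(g, Polygon)
             and g.area > 1e-12 * scale**2]
    if len(faces) != 2:
        raise TopologyError(
            f"split polyline must partition the outline into two fields, "
            f"got {len(faces)} faces")
    direction = split[-1] - split[0]
    sides = []
    for f in faces:
        rep = np.asarray(f.representative_point().coords[0])
        rel = rep - split[0]
        sides.append(direction[0] * rel[1] - direction[1] * rel[0])
    if sides[0] * sides[1] >= 0:
        raise TopologyError("cannot orient fields relative to the split line")
    anterior = faces[0] if sides[0] > 0 else faces[1]
    posterior = faces[1] if sides[0] > 0 else faces[0]
    return anterior, posterior


def _transect_width(geom_obj, x: float, ylo: float, yhi: float) -> float:
    line = LineString([(x, ylo - 1.0), (x, yhi + 1.0)])
    return float(geom_obj.intersection(line).length)


def measure_outline(outline: WingOutline) -> WingMeasurementRecord:
    """Take the ten raw measurements on a complete outline.

    Areas come from the shoelace formula (via polygon geometry), perimeters
    from polyline arc length, the maximal length from the extent along the
    principal axis, and all widths from the mid transect perpendicular to
    that axis. Field measurements require the radius split polyline; a
    missing split polyline is a topology error.
    """
    if outline.completeness != "complete":
        raise GeometryError("measure_outline requires a complete outline; "
                            "use extrapolate_tip for tip-missing outlines")
    geom.check_simple(outline.vertices)
    norm = _orientation_normalize(outline)
    verts = geom.ensure_ccw(norm.vertices)
    poly = Polygon(verts)

    xmin, xmax = verts[:, 0].min(), verts[:, 0].max()
    ymin, ymax = verts[:, 1].min(), verts[:, 1].max()
    length_max = float(xmax - xmin)
    xmid = 0.5 * (xmin + xmax)
    scale = outline.diameter

    width_mid = _transect_width(poly, xmid, ymin, ymax)
    if width_mid <= 0:
        raise GeometryError("outline has zero width at the mid transect")

    if norm.split_polyline is None:
        raise TopologyError("outline has no radius split polyline; field "
                            "measurements are undefined")
    anterior, posterior = _split_fields(poly, norm.split_polyline, scale)

    record = WingMeasurementRecord(
        taxon_id=outline.taxon_id,
        length_max=length_max,
        width_mid=width_mid,
        width_anterior_field=_transect_width(anterior, xmid, ymin, ymax),
        width_posterior_field=_transect_width(posterior, xmid, ymin, ymax),
        area_total=float(poly.area),
        area_anterior=float(anterior.area),
        area_posterior=float(posterior.area),
        perimeter_total=geom.polygon_perimeter(verts),
        perimeter_anterior=float(anterior.exterior.length),
        perimeter_posterior=float(posterior.exterior.length),
    )
    return record


def compute_parameters(record: WingMeasurementRecord) -> ShapeParameters:
    """Reduce the ten raw measurements to the four dimension-free ratios."""
    record.validate()
    for denom in ("length_max", "width_posterior_field", "area_posterior",
                  "perimeter_anterior"):
        if getattr(record, denom) <= 0:
            raise DataError(f"cannot form ratio: '{denom}' is non-positive")
    return ShapeParameters(
        ratio_wl=record.width_mid / record.length_max,
        ratio_field_width=(record.width_anterior_field
                           / record.width_posterior_field),
        ratio_field_area=record.area_anterior / record.area_posterior,
        circularity_anterior=geom.circularity(record.area_anterior,
                                              record.perimeter_anterior),
    )


def code_leaf_like(record: WingMeasurementRecord) -> LeafLike:
    """Binary coding: leaf-like iff the maximum wing width exceeds the
    thorax height; UNKNOWN when the thorax is not preserved."""
    if record.thorax_height is None:
        return LeafLike.UNKNOWN
    if record.thorax_height <= 0:
        raise DataError("thorax_height must be positive when present")
    return (LeafLike.LEAF_LIKE if record.width_mid > record.thorax_height
            else LeafLike.NOT_LEAF_LIKE)


# ---------------------------------------------------------------------------
# fossil completion


def _closure_curve(partial: WingOutline, n: int = 96) -> np.ndarray:
    """Curve completing the apex, from the chain's last point back to its
    first: a single circular arc when the two tangent-chord angles agree
    within 30 degrees, otherwise a tangent-continuous biarc."""
    if partial.open_endpoints is None or partial.end_tangents is None:
        raise ExtrapolationError("tip-missing outline lacks endpoint/tangent "
                                 "information")
    p_start, p_end = partial.open_endpoints            # chain[0], chain[-1]
    t_start, t_end = partial.end_tangents              # travel directions
    chord = p_start - p_end                            # closure: end -> start
    if np.hypot(*chord) < 1e-9:
        raise ExtrapolationError("open endpoints coincide; no closure arc")
    # tangent-chord angle at departure (chain end) and the one implied by
    # arrival at the chain start (an arc rotates its tangent by -2*alpha,
    # so the arrival tangent sits at -alpha from the chord)
    a_out = geom.signed_angle(chord, t_end)
    a_in = -geom.signed_angle(chord, t_start)
    mismatch = abs(a_out - a_in)
    if mismatch > math.radians(_BIARC_MISMATCH_DEG):
        return geom.biarc(p_end, t_end, p_start, t_start, n=n)
    alpha = 0.5 * (a_out + a_in)
    if abs(abs(alpha) - np.pi) < 1e-9:
        raise ExtrapolationError("end tangents antiparallel to the chord; "
                                 "no completion arc exists")
    return geom.arc_through(p_end, p_start, alpha, n=n)


def _extend_split_to(curve: np.ndarray, split: np.ndarray,
                     scale: float) -> np.ndarray:
    """Extend the radius polyline onto ``curve`` (the closure of the apex).

    The truncated split may have its cut end at either extremity (its
    orientation encodes which side is anterior and must be preserved), so
    both ends cast a ray along their local direction; whichever hits the
    closure is extended to the hit point.
    """
    closure = LineString(curve)
    for end, prev, head in ((split[-1], split[-2], True),
                            (split[0], split[1], False)):
        direction = end - prev
        norm = float(np.hypot(*direction))
        if norm == 0:
            continue
        direction = direction / norm
        ray = LineString([end - direction * 1e-6 * scale,
                          end + direction * 2.0 * scale])
        hit = closure.intersection(ray)
        if hit.is_empty:
            continue
        pts = ([np.asarray(g.coords[0]) for g in hit.geoms]
               if hasattr(hit, "geoms") else [np.asarray(hit.coords[0])])
        target = max(pts, key=lambda p: float(np.hypot(*(p - end))))
        return (np.vstack([split, target]) if head
                else np.vstack([target, split]))
    return split


def extrapolate_tip(partial: WingOutline):
    """Complete a tip-missing outline and measure it both ways.

    Returns ``(completed_outline, (record_chord, record_extrapolated))``:
    the first record is taken on the clipped polygon closed by the straight
    cut chord (no extrapolation), the second on the polygon closed by the
    completion arc. A complete outline passes through unchanged with two
    identical records.
    """
    if partial.completeness == "complete":
        record = measure_outline(partial)
        return partial, (record, record)

    closure = _closure_curve(partial)
    full_vertices = np.vstack([partial.vertices, closure[1:-1]])
    scale = partial.diameter
    split = partial.split_polyline
    split_ext = (_extend_split_to(closure, split, scale)
                 if split is not None else None)

    completed = WingOutline(vertices=full_vertices,
                            split_polyline=split_ext,
                            completeness="complete",
                            taxon_id=partial.taxon_id)
    chord_closed = WingOutline(vertices=partial.vertices,
                               split_polyline=split,
                               completeness="complete",
                               taxon_id=partial.taxon_id)
    record_extrap = measure_outline(completed)
    record_chord = measure_outline(chord_closed)
    return completed, (record_chord, record_extrap)


def parameters_from_outline(outline: WingOutline) -> ShapeParameters:
    """Convenience: measure a complete outline and reduce to descriptors."""
    return compute_parameters(measure_outline(outline))
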