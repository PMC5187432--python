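"""Synthetic katydid populations and wing outlines.

The comparative dataset behind the analysis is a table of macropterous
katydid species with four dimension-free tegmen shape descriptors, a
leaf-mimicking/non-mimicking dichotomy, and a reference subfamily
(Pterochrozinae) that is entirely leaf-mimicking. This module generates
such tables from a two-component normal structure — one component for
leaf-mimicking forms (including all Pterochrozinae), one for the rest —
plus geometrically consistent raw measurements, full wing outlines from a
two-lobe superellipse family, and tip-truncated outlines emulating a
fossil whose wing apex is missing.

Default component means and spreads are chosen to be realistic for katydid
tegmina (mimicking wings broad, width/length near 0.36 with nearly equal
anterior/posterior fields; non-mimicking wings narrow and field-asymmetric)
and to place the two components three standard deviations apart on every
descriptor, the separation the downstream mixture analysis is designed to
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import geometry as geom
from .errors import ConfigurationError, GeometryError, InfeasibleShapeError
from .morphometry import (
    DESCRIPTOR_NAMES,
    ShapeParameters,
    WingOutline,
    measure_outline,
)

__all__ = [
    "ComponentSettings",
    "SyntheticPopulationConfig",
    "draw_shape_parameters",
    "synthesize_outline",
    "truncate_tip",
]

_SUBFAMILIES_NON_MIMICKING = (
    "Phaneropterinae", "Conocephalinae", "Tettigoniinae",
    "Listroscelidinae", "Saginae",
)
_SUBFAMILIES_MIMICKING_OTHER = ("Pseudophyllinae", "Mecopodinae")

# superellipse exponent search bracket for outline synthesis
_P_LO, _P_HI = 0.2, 60.0


@dataclass
class ComponentSettings:
    """Per-descriptor normal parameters for one mixture component."""

    mean: Dict[str, float]
    sd: Dict[str, float]

    def validate(self, label: str) -> "ComponentSettings":
        for name in DESCRIPTOR_NAMES:
            if name not in self.mean or name not in self.sd:
                raise ConfigurationError(
                    f"{label}: missing mean/sd for descriptor '{name}'")
            if self.mean[name] <= 0:
                raise ConfigurationError(
                    f"{label}: mean of '{name}' must be positive")
            if self.sd[name] <= 0:
                raise ConfigurationError(
                    f"{label}: sd of '{name}' must be positive")
        if not (0.0 < self.mean["circularity_anterior"] <= 1.0):
            raise ConfigurationError(
                f"{label}: circularity_anterior mean must lie in (0, 1]")
        return self


def _default_mimicking() -> ComponentSettings:
    # broad leaf-like tegmen: ~2.8x longer than wide, symmetric fields
    return ComponentSettings(
        mean={"ratio_wl": 0.36, "ratio_field_width": 1.0,
              "ratio_field_area": 1.0, "circularity_anterior": 0.33},
        sd={"ratio_wl": 0.05, "ratio_field_width": 0.15,
            "ratio_field_area": 0.15, "circularity_anterior": 0.05},
    )


def _default_non_mimicking() -> ComponentSettings:
    # narrow tegmen, anterior field smaller; means 3 sd from the mimicking
    # component on every descriptor
    return ComponentSettings(
        mean={"ratio_wl": 0.21, "ratio_field_width": 0.55,
              "ratio_field_area": 0.55, "circularity_anterior": 0.18},
        sd={"ratio_wl": 0.05, "ratio_field_width": 0.15,
            "ratio_field_area": 0.15, "circularity_anterior": 0.05},
    )


@dataclass
class SyntheticPopulationConfig:
    """Study-design parameters for one synthetic species table."""

    n_species: int = 253
    mixing_fraction: float = 0.3
    mimicking: ComponentSettings = field(default_factory=_default_mimicking)
    non_mimicking: ComponentSettings = field(
        default_factory=_default_non_mimicking)
    n_pterochrozinae: int = 20
    rng_seed: int = 0
    length_scale_range: Tuple[float, float] = (25.0, 60.0)  # mm
    correlation: Optional[np.ndarray] = None  # across the 4 descriptors

    def validate(self) -> "SyntheticPopulationConfig":
        if not (isinstance(self.n_species, (int, np.integer))
                and self.n_species > 0):
            raise ConfigurationError("n_species must be a positive integer")
        if not (0.0 <= self.mixing_fraction <= 1.0):
            raise ConfigurationError("mixing_fraction must lie in [0, 1]")
        self.mimicking.validate("mimicking")
        self.non_mimicking.validate("non_mimicking")
        n_mim = self.n_mimicking
        if self.n_pterochrozinae < 0 or self.n_pterochrozinae > n_mim:
            raise ConfigurationError(
                f"n_pterochrozinae must lie in [0, {n_mim}] "
                f"(round(mixing_fraction * n_species))")
        lo, hi = self.length_scale_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                "length_scale_range must be a positive interval (lo <= hi)")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (4, 4) or not np.allclose(c, c.T):
                raise ConfigurationError(
                    "correlation must be a symmetric 4x4 matrix")
        return self

    @property
    def n_mimicking(self) -> int:
        # deterministic group size: makes counts assertable
        return int(round(self.mixing_fraction * self.n_species))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def _draw_component(rng: np.random.Generator, settings: ComponentSettings,
                    n: int, correlation: Optional[np.ndarray]) -> np.ndarray:
    """Draw n rows of the 4 descriptors; circularity redrawn into (0, 1]."""
    means = np.array([settings.mean[k] for k in DESCRIPTOR_NAMES])
    sds = np.array([settings.sd[k] for k in DESCRIPTOR_NAMES])
    if correlation is None:
        corr = np.eye(4)
    else:
        corr = np.asarray(correlation, dtype=float)
    chol = np.linalg.cholesky(corr)
    out = np.empty((n, 4))
    filled = 0
    while filled < n:
        z = rng.standard_normal((n - filled, 4)) @ chol.T
        draws = means + sds * z
        # all descriptors must be positive; circularity bounded by 1
        ok = np.all(draws > 0, axis=1) & (draws[:, 3] <= 1.0)
        good = draws[ok]
        out[filled:filled + len(good)] = good
        filled += len(good)
    return out


def draw_shape_parameters(config: SyntheticPopulationConfig) -> pd.DataFrame:
    """Draw one synthetic species table.

    Returns a DataFrame with taxon_id, subfamily, is_mimicking,
    is_pterochrozinae, the four descriptors, thorax_height, the leaf_like
    binary, and ten geometrically consistent raw-measurement columns.
    Reproducible given ``config.rng_seed``; rows are ordered mimicking
    first (Pterochrozinae at the top).
    """
    config.validate()
    rng = config.rng()
    n = config.n_species
    n_mim = config.n_mimicking
    n_non = n - n_mim

    mim = _draw_component(rng, config.mimicking, n_mim, config.correlation)
    non = _draw_component(rng, config.non_mimicking, n_non,
                          config.correlation)
    values = np.vstack([mim, non]) if n_mim else non
    is_mim = np.array([True] * n_mim + [False] * n_non)
    is_ptero = np.array([i < config.n_pterochrozinae for i in range(n)])

    subfamily = np.empty(n, dtype=object)
    subfamily[:config.n_pterochrozinae] = "Pterochrozinae"
    other_mim = rng.choice(_SUBFAMILIES_MIMICKING_OTHER,
                           size=n_mim - config.n_pterochrozinae)
    subfamily[config.n_pterochrozinae:n_mim] = other_mim
    subfamily[n_mim:] = rng.choice(_SUBFAMILIES_NON_MIMICKING, size=n_non)

    table = pd.DataFrame(values, columns=list(DESCRIPTOR_NAMES))
    table.insert(0, "taxon_id", [f"taxon_{i:04d}" for i in range(n)])
    table.insert(1, "subfamily", subfamily)
    table.insert(2, "is_mimicking", is_mim)
    table.insert(3, "is_pterochrozinae", is_ptero)

    _append_raw_measurements(table, config, rng)
    return table


def _append_raw_measurements(table: pd.DataFrame,
                             config: SyntheticPopulationConfig,
                             rng: np.random.Generator) -> None:
    """Add thorax height, leaf-like coding and ten raw measurements that are
    consistent with the drawn descriptors by construction."""
    n = len(table)
    lo, hi = config.length_scale_range
    length = rng.uniform(lo, hi, size=n)
    w = table["ratio_wl"].to_numpy()
    rw = table["ratio_field_width"].to_numpy()
    ra = table["ratio_field_area"].to_numpy()
    circ = table["circularity_anterior"].to_numpy()

    width_mid = w * length
    width_ant = width_mid * rw / (1.0 + rw)
    width_post = width_mid / (1.0 + rw)
    # lobe fill factor: area of a field relative to its bounding box
    fill = 0.7
    area_ant = fill * length * width_ant
    area_post = area_ant / ra
    perim_ant = np.sqrt(4.0 * np.pi * area_ant / circ)
    # posterior field circularity is not a descriptor; reuse the anterior one
    perim_post = np.sqrt(4.0 * np.pi * area_post / circ)
    # the shared radius chord is interior: not part of the outer boundary
    perim_total = (perim_ant - length) + (perim_post - length)
    perim_total = np.maximum(perim_total, 2.0 * length)

    # thorax height: mimicking wings are wider than the thorax is tall
    ratio = np.where(table["is_mimicking"],
                     rng.lognormal(np.log(1.5), 0.25, size=n),
                     rng.lognormal(np.log(0.6), 0.25, size=n))
    thorax = width_mid / ratio

    table["thorax_height"] = thorax
    table["leaf_like"] = width_mid > thorax
    table["length_max"] = length
    table["width_mid"] = width_mid
    table["width_anterior_field"] = width_ant
    table["width_posterior_field"] = width_post
    table["area_total"] = area_ant + area_post
    table["area_anterior"] = area_ant
    table["area_posterior"] = area_post
    table["perimeter_total"] = perim_total
    table["perimeter_anterior"] = perim_ant
    table["perimeter_posterior"] = perim_post


# ---------------------------------------------------------------------------
# outline synthesis


def _lobe_metrics(length: float, height: float, p: float,
                  n: int = 257) -> Tuple[float, float]:
    """(area, closed perimeter incl. chord) of one superellipse field."""
    lobe = geom.superellipse_lobe(length, height, p, n=n)
    area = abs(geom.polygon_area(lobe))
    perim = geom.polygon_perimeter(lobe, closed=False) + length
    return area, perim


def _solve_exponent_for_circularity(length: float, height: float,
                                    target: float) -> float:
    def circ_of(p: float) -> float:
        area, perim = _lobe_metrics(length, height, p)
        return geom.circularity(area, perim)

    lo, hi = circ_of(_P_LO), circ_of(_P_HI)
    lo, hi = min(lo, hi), max(lo, hi)
    if not (lo <= target <= hi):
        raise InfeasibleShapeError(
            f"circularity {target:.4g} unreachable for this width/length "
            f"geometry; achievable range is [{lo:.4g}, {hi:.4g}]",
            achievable=(lo, hi))
    return brentq(lambda p: circ_of(p) - target, _P_LO, _P_HI, xtol=1e-10)


def _solve_exponent_for_area(length: float, height: float,
                             target_area: float) -> float:
    def area_of(p: float) -> float:
        return _lobe_metrics(length, height, p)[0]

    lo, hi = area_of(_P_LO), area_of(_P_HI)
    if not (min(lo, hi) <= target_area <= max(lo, hi)):
        raise InfeasibleShapeError(
            f"posterior field area {target_area:.4g} unreachable; "
            f"achievable range is [{min(lo, hi):.4g}, {max(lo, hi):.4g}]",
            achievable=(min(lo, hi), max(lo, hi)))
    return brentq(lambda p: area_of(p) - target_area, _P_LO, _P_HI,
                  xtol=1e-10)


def synthesize_outline(params: ShapeParameters, length: float,
                       taxon_id: str = "synthetic",
                       n_per_lobe: int = 257) -> WingOutline:
    """Construct a wing outline realising the four descriptors.

    The outline family is two superellipse lobes (anterior above, posterior
    below) sharing the straight radius chord from (0, 0) to (length, 0).
    Lobe heights follow from the width descriptors; each lobe's exponent is
    solved numerically so the measured anterior circularity and field-area
    ratio hit the targets. Descriptor combinations outside the family's
    reach raise :class:`InfeasibleShapeError` with the achievable range.

    The returned outline is a simple closed polygon whose measured
    descriptors match ``params`` to about 1e-3 relative; the split polyline
    runs (0,0) -> (length,0), anterior field on its left.
    """
    if params.circularity_anterior > 1.0:
        raise InfeasibleShapeError(
            "circularity above 1 violates the isoperimetric bound",
            achievable=(0.0, 1.0))
    params.validate()
    if length <= 0:
        raise GeometryError("length must be positive")
    w, rw = params.ratio_wl, params.ratio_field_width
    if w * length >= length:  # total width must stay below the length
        raise InfeasibleShapeError(
            "ratio_wl >= 1 leaves no long axis for this outline family",
            achievable=(0.0, 1.0))
    h_ant = w * length * rw / (1.0 + rw)
    h_post = w * length / (1.0 + rw)

    p_ant = _solve_exponent_for_circularity(length, h_ant,
                                            params.circularity_anterior)
    area_ant, _ = _lobe_metrics(length, h_ant, p_ant)
    p_post = _solve_exponent_for_area(length, h_post,
                                      area_ant / params.ratio_field_area)

    top = geom.superellipse_lobe(length, h_ant, p_ant, n=n_per_lobe)
    bottom = geom.superellipse_lobe(length, h_post, p_post, n=n_per_lobe)
    bottom = bottom[::-1].copy()
    bottom[:, 1] *= -1.0
    vertices = np.vstack([top, bottom[1:-1]])  # CCW? top L->R, bottom R->L
    vertices = geom.ensure_ccw(vertices)
    split = np.array([[0.0, 0.0], [0.5 * length, 0.0], [length, 0.0]])
    return WingOutline(vertices=vertices, split_polyline=split,
                       completeness="complete", taxon_id=taxon_id)


# ---------------------------------------------------------------------------
# truncation


def _clip_polyline_halfplane(polyline: np.ndarray,
                             x_cut: float) -> np.ndarray:
    """Keep the connected run of the polyline with x <= x_cut, inserting
    the crossing point where a segment straddles the cut line. Preserves
    the original point order (orientation is meaningful: the anterior
    field lies left of the directed split line)."""
    inside = polyline[:, 0] <= x_cut
    if not inside.any():
        raise GeometryError("truncation removed the entire split line")
    out = []
    for i in range(len(polyline) - 1):
        a, b = polyline[i], polyline[i + 1]
        if inside[i]:
            out.append(a)
        if inside[i] != inside[i + 1] and abs(b[0] - a[0]) > 0:
            t = (x_cut - a[0]) / (b[0] - a[0])
            out.append(a + t * (b - a))
    if inside[-1]:
        out.append(polyline[-1])
    clipped = np.asarray(out)
    if len(clipped) < 2:
        raise GeometryError("truncated split line is degenerate")
    return clipped


def truncate_tip(outline: WingOutline, fraction_removed: float) -> WingOutline:
    """Clip the wing apex, emulating a fossil with a missing tip.

    The cut line is perpendicular to the long axis at
    ``(1 - fraction_removed) * length`` from the wing base (the base is the
    low-x end after orientation normalisation). Records the two open
    endpoints and the boundary travel directions there so the apex can be
    re-completed by :func:`leafmorph.morphometry.extrapolate_tip`.
    """
    if not (0.0 < fraction_removed < 0.5):
        raise ConfigurationError(
            "fraction_removed must lie strictly between 0 and 0.5")
    if outline.completeness != "complete":
        raise GeometryError("can only truncate a complete outline")

    angle = geom.principal_angle(outline.vertices)
    verts = geom.ensure_ccw(geom.rotate(outline.vertices, -angle))
    split = (geom.rotate(outline.split_polyline, -angle)
             if outline.split_polyline is not None else None)

    xmin, xmax = verts[:, 0].min(), verts[:, 0].max()
    x_cut = xmin + (1.0 - fraction_removed) * (xmax - xmin)

    inside = verts[:, 0] <= x_cut
    if inside.all() or not inside.any():
        raise GeometryError("cut line does not intersect the outline")

    n = len(verts)
    crossings = []
    for i in range(n):
        j = (i + 1) % n
        if inside[i] != inside[j]:
            a, b = verts[i], verts[j]
            t = (x_cut - a[0]) / (b[0] - a[0])
            point = a + t * (b - a)
            direction = (b - a) / np.hypot(*(b - a))
            crossings.append((i, point, direction, inside[i]))
    if len(crossings) != 2:
        raise GeometryError(
            f"cut line crosses the outline {len(crossings)} times; "
            "expected exactly 2 (apex must be single-lobed)")

    entry = next(c for c in crossings if not c[3])  # outside -> inside
    exit_ = next(c for c in crossings if c[3])      # inside -> outside
    chain = [entry[1]]
    i = (entry[0] + 1) % n
    while i != (exit_[0] + 1) % n:
        chain.append(verts[i])
        i = (i + 1) % n
    chain.append(exit_[1])
    chain = np.asarray(chain)

    if split is not None:
        split = _clip_polyline_halfplane(split, x_cut)

    return WingOutline(
        vertices=chain,
        split_polyline=split,
        completeness="tip_missing",
        open_endpoints=np.array([entry[1], exit_[1]]),
        end_tangents=np.array([entry[2], exit_[2]]),
        taxon_id=outline.taxon_id,
    )
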