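"""PCA morphospace of tegmen shape descriptors.

The ordination is a correlation-matrix PCA (each descriptor centred and
scaled to unit standard deviation) of the modern species table. Groups —
mimetic (M) and non-mimetic (nM) wings under the leaf-like binary — are
summarised in the first factorial plane by their centroids and
normal-theory confidence ellipses (chi-square quantile with 2 degrees of
freedom on the group score covariance). Query specimens (the fossil, or
other taxa of interest) are projected as supplementary individuals by
default: they are centred and scaled with the training statistics and
multiplied by the loadings without influencing the axes. An "active" mode
that refits the axes with the queries included is also provided.

Loadings signs are fixed so the largest-magnitude weight on each axis is
positive, making the ordination deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "MorphospaceModel",
    "GroupEllipse",
    "fit_pca",
    "project",
    "group_ellipse",
    "centroid_distances",
]

_TIE_RTOL = 1e-9


@dataclass
class MorphospaceModel:
    """Correlation-PCA model: loadings, eigenvalues and training scores."""

    variable_names: List[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray      # (p, p), columns are axes
    eigenvalues: np.ndarray   # nonincreasing
    scores: np.ndarray        # (n, p)
    explained_fraction: np.ndarray
    taxon_ids: Optional[List[str]] = None

    def to_dict(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
        }


@dataclass
class GroupEllipse:
    """Confidence ellipse of one group's cloud in the first factorial plane."""

    group_label: str
    center: np.ndarray
    semi_axes: np.ndarray     # lengths, major first
    orientation: float        # radians, major axis vs PC1
    coverage_level: float
    degenerate: bool = False

    def contains(self, point) -> bool:
        """Whether a 2D point lies inside (or on) the ellipse."""
        p = np.asarray(point, dtype=float) - self.center
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = np.array([c * p[0] + s * p[1], -s * p[0] + c * p[1]])
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            return False
        return float((u[0] / a) ** 2 + (u[1] / b) ** 2) <= 1.0 + 1e-12

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "orientation": float(self.orientation),
            "coverage_level": float(self.coverage_level),
            "degenerate": bool(self.degenerate),
        }


def _extract_matrix(table: pd.DataFrame,
                    variables: Sequence[str]) -> np.ndarray:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise DataError(f"variables absent from table: {missing}")
    block = table.loc[:, list(variables)]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise DataError(
            f"missing values in variables {bad}; imputation is not "
            "performed — drop or complete those taxa first")
    return block.to_numpy(dtype=float)


def fit_pca(table: pd.DataFrame, variables: Sequence[str],
            taxon_id_column: str = "taxon_id") -> MorphospaceModel:
    """Correlation-matrix PCA of the selected descriptors.

    Computed by singular value decomposition of the standardised data
    matrix (SDs with ddof=1, so eigenvalues sum to the number of
    variables and match the correlation-matrix eigendecomposition).
    """
    variables = list(variables)
    if len(variables) < 2:
        raise DataError("PCA needs at least 2 variables")
    x = _extract_matrix(table, variables)
    n = x.shape[0]
    if n < 3:
        raise DataError("PCA needs at least 3 taxa")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    constant = np.flatnonzero(scale <= 0)
    if constant.size:
        names = [variables[i] for i in constant]
        raise DataError(f"constant variable(s) {names}: correlation PCA "
                        "is undefined for zero-variance inputs")
    z = (x - center) / scale
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    # deterministic sign: largest-|weight| entry of each axis positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = z @ loadings
    explained = eigenvalues / eigenvalues.sum()
    ids = (table[taxon_id_column].tolist()
           if taxon_id_column in table.columns else None)
    return MorphospaceModel(
        variable_names=variables, center=center, scale=scale,
        loadings=loadings, eigenvalues=eigenvalues, scores=scores,
        explained_fraction=explained, taxon_ids=ids)


def project(model: MorphospaceModel, query) -> np.ndarray:
    """Project a query onto the model axes as a supplementary individual.

    ``query`` may be a mapping of variable name to value, a pandas Series,
    or an array in the model's variable order. Returns the full-axis
    coordinate vector (2D position = first two entries). A training row
    projects exactly onto its stored score.
    """
    if isinstance(query, (dict, pd.Series)):
        missing = [v for v in model.variable_names if v not in query]
        if missing:
            raise DataError(f"query lacks variables: {missing}")
        vec = np.array([float(query[v]) for v in model.variable_names])
    else:
        vec = np.asarray(query, dtype=float).ravel()
        if vec.size != len(model.variable_names):
            raise DataError(
                f"query has {vec.size} values; model expects "
                f"{len(model.variable_names)}")
    if not np.all(np.isfinite(vec)):
        raise DataError("query contains non-finite values")
    return ((vec - model.center) / model.scale) @ model.loadings


def group_ellipse(model: MorphospaceModel, labels: Sequence,
                  level: float = 0.95) -> Dict[str, GroupEllipse]:
    """Normal-theory confidence ellipse per group in the PC1-PC2 plane.

    Axes follow the eigenvectors of the group's 2D score covariance;
    semi-axis lengths are sqrt(eigenvalue * chi2.ppf(level, 2)). Groups
    with singular covariance yield a degenerate (segment-like) ellipse
    with a warning flag rather than an error.
    """
    if not (0.0 < level < 1.0):
        raise DataError("coverage level must lie in (0, 1)")
    labels = np.asarray(labels)
    if labels.shape[0] != model.scores.shape[0]:
        raise DataError("one group label per training taxon required")
    quantile = stats.chi2.ppf(level, df=2)
    out: Dict[str, GroupEllipse] = {}
    for label in pd.unique(labels):
        pts = model.scores[labels == label, :2]
        if pts.shape[0] < 3:
            raise DataError(f"group {label!r} needs at least 3 members")
        cov = np.cov(pts, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
        semi = np.sqrt(np.clip(evals, 0.0, None) * quantile)
        major = evecs[:, 0]
        out[str(label)] = GroupEllipse(
            group_label=str(label),
            center=pts.mean(axis=0),
            semi_axes=semi,
            orientation=float(np.arctan2(major[1], major[0])),
            coverage_level=level,
            degenerate=degenerate)
    return out


def centroid_distances(model: MorphospaceModel, query_coords,
                       labels: Sequence,
                       ellipses: Optional[Dict[str, GroupEllipse]] = None
                       ) -> dict:
    """Euclidean distances from a query to each group centroid (PC1-PC2).

    Returns ``{"distances": {...}, "nearest": label or None, "tie": bool,
    "inside": {...}}``. Ties (equal distances within relative tolerance)
    are reported explicitly with ``nearest=None`` rather than broken
    silently.
    """
    q = np.asarray(query_coords, dtype=float).ravel()[:2]
    labels = np.asarray(labels)
    distances: Dict[str, float] = {}
    for label in pd.unique(labels):
        pts = model.scores[labels == label, :2]
        centroid = pts.mean(axis=0)
        distances[str(label)] = float(np.hypot(*(q - centroid)))
    ranked = sorted(distances.items(), key=lambda kv: kv[1])
    tie = (len(ranked) > 1
           and abs(ranked[0][1] - ranked[1][1])
           <= _TIE_RTOL * max(ranked[1][1], 1e-300))
    inside = {}
    if ellipses:
        inside = {name: ell.contains(q) for name, ell in ellipses.items()}
    return {
        "distances": distances,
        "nearest": None if tie else ranked[0][0],
        "tie": tie,
        "inside": inside,
    }
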