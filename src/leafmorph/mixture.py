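"""Least-squares normal-CDF mixture fitting on empirical distributions.

Each shape descriptor's empirical cumulative distribution (Hazen plotting
positions, no binning) is fitted with:

* a one-component normal CDF
      F(x) = 1/2 * (1 + erf((x - A1) / (A2 * sqrt(2)))),
  where A1 is the mean and A2 the standard deviation; and
* a two-component model whose first mean A1 is frozen at the value fitted
  on the all-leaf-mimicking reference subfamily (Pterochrozinae),
      F(x) = (1 - A5) * Phi((x - A1)/A2) + A5 * Phi((x - A3)/A4),
  with A2, A4 > 0 the component standard deviations and A5 in [0, 1] the
  weight of the free (non-mimicking) component.

The models are nested (A5 = 0 recovers the one-component model exactly),
so they are compared with the extra sum-of-squares F test (significance
threshold P < 0.01) together with decreases in AIC and BIC in their
least-squares Gaussian-error forms. The two-component model is preferred
only when all three criteria agree.

Note the F test treats the CDF-fit residuals as independent, which they
are not (cumulative sums); the procedure is anticonservative and is
reported as such in the pipeline output.

The sharing fraction used to classify a query specimen (the fossil) is the
proportion of a group's species whose descriptor value falls inside a
stated interval around the query value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import erf

from .errors import DataError, FitError, InsufficientReferenceError

__all__ = [
    "EmpiricalCDF",
    "NormalCDFFit",
    "ForcedTwoComponentFit",
    "ModelComparison",
    "SharingRule",
    "empirical_cdf",
    "normal_cdf",
    "two_component_cdf",
    "fit_one_component",
    "fit_forced_two_component",
    "fit_pterochrozinae_reference",
    "compare_models",
    "sharing_fraction",
]

P_THRESHOLD = 0.01
_FTOL = 1e-10
_MAX_NFEV = 500
_SQRT2PI = np.sqrt(2.0 * np.pi)


def _normal_pdf(x, mean, sd):
    z = (np.asarray(x, dtype=float) - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * _SQRT2PI)
_SD_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# model functions


def normal_cdf(x, mean, sd):
    """One-component model: 1/2 * (1 + erf((x - mean)/(sd*sqrt(2))))."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + erf((x - mean) / (sd * np.sqrt(2.0))))


def two_component_cdf(x, a1, a2, a3, a4, a5):
    """Two-component model with the first mean a1 frozen upstream."""
    return (1.0 - a5) * normal_cdf(x, a1, a2) + a5 * normal_cdf(x, a3, a4)


# ---------------------------------------------------------------------------
# types


@dataclass
class EmpiricalCDF:
    """Sorted values with Hazen plotting positions (i - 0.5)/n."""

    values: np.ndarray
    probs: np.ndarray
    n: int

    def validate(self) -> "EmpiricalCDF":
        if self.n < 5:
            raise DataError(f"need at least 5 observations, got {self.n}")
        if np.any(np.diff(self.values) < 0):
            raise DataError("empirical CDF values must be nondecreasing")
        if np.any(np.diff(self.probs) <= 0) or np.any(
                (self.probs <= 0) | (self.probs >= 1)):
            raise DataError("plotting positions must increase strictly "
                            "inside (0, 1)")
        return self


@dataclass
class NormalCDFFit:
    """One-component fit: A1 mean, A2 standard deviation."""

    a1: float
    a2: float
    rss: float
    n: int
    n_params: int = 2

    def predict(self, x):
        return normal_cdf(x, self.a1, self.a2)


@dataclass
class ForcedTwoComponentFit:
    """Two-component fit with A1 frozen at the reference (Pterochrozinae)
    mean; free parameters A2, A3, A4, A5."""

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    rss: float
    n: int
    n_params: int = 4

    def predict(self, x):
        return two_component_cdf(x, self.a1, self.a2, self.a3, self.a4,
                                 self.a5)


@dataclass
class ModelComparison:
    """Extra sum-of-squares F test plus AIC/BIC deltas for the nested pair."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    aic_one: float
    aic_two: float
    bic_one: float
    bic_two: float
    preferred: str  # "one_component" | "two_component"

    @property
    def delta_aic(self) -> float:
        return self.aic_two - self.aic_one

    @property
    def delta_bic(self) -> float:
        return self.bic_two - self.bic_one


@dataclass
class SharingRule:
    """Interval rule defining when a group member 'shares' the query value.

    ``kind`` is 'half_width' (fixed half-width in descriptor units) or
    'k_sd' (half-width = k * reference SD, resolved by the caller).
    """

    kind: str = "half_width"
    half_width: float = 0.0
    description: str = ""

    def interval(self, query: float) -> Tuple[float, float]:
        if self.half_width < 0:
            raise DataError("sharing half-width must be nonnegative")
        return query - self.half_width, query + self.half_width


# ---------------------------------------------------------------------------
# operations


def empirical_cdf(values: Sequence[float]) -> EmpiricalCDF:
    """Empirical CDF with Hazen plotting positions; ties kept as points.

    Small inputs (n >= 2) are allowed here so plotting positions can be
    inspected; the fitting operations enforce n >= 5 via ``validate``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise DataError("empirical CDF input contains non-finite values")
    n = len(x)
    if n < 2:
        raise DataError(f"need at least 2 observations, got {n}")
    order = np.sort(x)
    probs = (np.arange(1, n + 1) - 0.5) / n
    return EmpiricalCDF(values=order, probs=probs, n=n)


def fit_one_component(ecdf: EmpiricalCDF) -> NormalCDFFit:
    """Least-squares fit of the one-component normal CDF.

    Initialised at the sample mean and SD; bounded so the SD stays
    positive.
    """
    ecdf.validate()
    x, p = ecdf.values, ecdf.probs
    sd0 = float(np.std(x, ddof=1))
    if sd0 <= 0:
        raise FitError("degenerate data: zero variance")
    theta0 = np.array([float(np.mean(x)), sd0])

    def residuals(theta):
        return normal_cdf(x, theta[0], theta[1]) - p

    def jacobian(theta):
        a1, a2 = theta
        pdf = _normal_pdf(x, a1, a2)
        return np.column_stack([-pdf, -pdf * (x - a1) / a2])

    result = optimize.least_squares(
        residuals, theta0, jac=jacobian,
        bounds=([-np.inf, _SD_FLOOR], [np.inf, np.inf]),
        ftol=_FTOL, xtol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV)
    if not result.success:
        raise FitError(f"one-component fit did not converge: "
                       f"{result.message} (nfev={result.nfev})")
    rss = float(result.cost * 2.0)
    return NormalCDFFit(a1=float(result.x[0]), a2=float(result.x[1]),
                        rss=rss, n=ecdf.n)


def _two_component_starts(x: np.ndarray, one_fit: Optional[NormalCDFFit]):
    sd = float(np.std(x, ddof=1))
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    starts = [np.array([sd, a3, sd, a5])
              for a5 in (0.25, 0.5, 0.75) for a3 in (q25, q50, q75)]
    if one_fit is not None:
        # A5 = 1 start reproducing the one-component optimum exactly:
        # guarantees the nested fit can never end worse than the null
        starts.append(np.array([sd, one_fit.a1, one_fit.a2, 1.0]))
    return starts


def fit_forced_two_component(
        ecdf: EmpiricalCDF, forced_mean: float,
        one_fit: Optional[NormalCDFFit] = None,
        extra_starts: Sequence[np.ndarray] = ()) -> ForcedTwoComponentFit:
    """Least-squares fit of the forced-mean two-component model.

    A1 is frozen at ``forced_mean``; A2, A4 > 0 and A5 in [0, 1] via box
    constraints. Multi-start over A5 in {0.25, 0.5, 0.75} crossed with A3
    in {q25, q50, q75} of the data (plus, when the one-component fit is
    supplied, a start at its solution with A5 = 1, which makes the nesting
    inequality rss_two <= rss_one hold in practice). The best converged
    start wins.
    """
    ecdf.validate()
    if not np.isfinite(forced_mean):
        raise DataError("forced_mean must be finite")
    x, p = ecdf.values, ecdf.probs
    if float(np.std(x, ddof=1)) <= 0:
        raise FitError("degenerate data: zero variance")

    def residuals(theta):
        a2, a3, a4, a5 = theta
        return two_component_cdf(x, forced_mean, a2, a3, a4, a5) - p

    def jacobian(theta):
        a2, a3, a4, a5 = theta
        pdf1 = _normal_pdf(x, forced_mean, a2)
        pdf2 = _normal_pdf(x, a3, a4)
        return np.column_stack([
            -(1.0 - a5) * pdf1 * (x - forced_mean) / a2,
            -a5 * pdf2,
            -a5 * pdf2 * (x - a3) / a4,
            normal_cdf(x, a3, a4) - normal_cdf(x, forced_mean, a2),
        ])

    lower = np.array([_SD_FLOOR, -np.inf, _SD_FLOOR, 0.0])
    upper = np.array([np.inf, np.inf, np.inf, 1.0])
    best = None
    diagnostics = []
    starts = list(_two_component_starts(x, one_fit)) + list(extra_starts)
    for theta0 in starts:
        try:
            result = optimize.least_squares(
                residuals, np.clip(theta0, lower, upper), jac=jacobian,
                bounds=(lower, upper), ftol=_FTOL, xtol=1e-12, gtol=1e-12,
                max_nfev=_MAX_NFEV)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {theta0}: {exc}")
            continue
        if not np.isfinite(result.cost):
            diagnostics.append(f"start {theta0}: non-finite cost "
                               f"({result.message})")
            continue
        # an iteration-capped start still yields a usable candidate; the
        # flat near-degenerate surfaces of the null case hit the cap while
        # already sitting at the optimum
        if best is None or result.cost < best.cost:
            best = result
    if best is None:
        raise FitError("all two-component starts failed:\n"
                       + "\n".join(diagnostics))
    a2, a3, a4, a5 = (float(v) for v in best.x)
    return ForcedTwoComponentFit(a1=float(forced_mean), a2=a2, a3=a3, a4=a4,
                                 a5=a5, rss=float(best.cost * 2.0), n=ecdf.n)


def fit_pterochrozinae_reference(table: pd.DataFrame,
                                 descriptor: str) -> NormalCDFFit:
    """One-component fit restricted to the reference subfamily rows.

    The resulting mean A1 characterises leaf-mimicking tegmina and is the
    frozen mean of the two-component model downstream.
    """
    if "is_pterochrozinae" not in table.columns:
        raise DataError("table lacks an 'is_pterochrozinae' column")
    if descriptor not in table.columns:
        raise DataError(f"table lacks descriptor column '{descriptor}'")
    subset = table.loc[table["is_pterochrozinae"].astype(bool), descriptor]
    if len(subset) < 5:
        raise InsufficientReferenceError(
            f"need at least 5 Pterochrozinae rows to fit the reference "
            f"component, got {len(subset)}")
    return fit_one_component(empirical_cdf(subset.to_numpy()))


def _aic_bic(rss: float, n: int, k: int) -> Tuple[float, float]:
    # least-squares Gaussian-error form; k + 1 counts the error variance
    rss = max(rss, 1e-300)
    base = n * np.log(rss / n)
    return base + 2.0 * (k + 1), base + (k + 1) * np.log(n)


def compare_models(one: NormalCDFFit, two: ForcedTwoComponentFit,
                   ecdf: Optional[EmpiricalCDF] = None,
                   forced_mean: Optional[float] = None) -> ModelComparison:
    """Extra sum-of-squares F test plus AIC/BIC for the nested model pair.

    F = ((rss1 - rss2)/(4 - 2)) / (rss2/(n - 4)), referred to F(2, n - 4).
    The two-component model is preferred only when P < 0.01 AND its AIC
    and BIC both decrease. If the optimizer violated nesting
    (rss2 > rss1), the two-component model is refitted from the
    one-component solution when the data are supplied; a persistent
    violation is a fit error.
    """
    if one.n != two.n:
        raise DataError("model comparison requires fits on the same sample")
    n = one.n
    if n <= 4:
        raise DataError("need n > 4 for the extra sum-of-squares test")
    rss1, rss2 = one.rss, two.rss
    if rss2 > rss1 * (1.0 + 1e-12):
        if ecdf is not None:
            refit = fit_forced_two_component(
                ecdf, two.a1 if forced_mean is None else forced_mean,
                one_fit=one)
            if refit.rss <= rss1 * (1.0 + 1e-12):
                return compare_models(one, refit)
        raise FitError("nesting violated: two-component rss exceeds "
                       "one-component rss even after refit")

    df_num, df_den = 2, n - 4
    f_stat = max((rss1 - rss2) / df_num, 0.0) / (rss2 / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    aic1, bic1 = _aic_bic(rss1, n, one.n_params)
    aic2, bic2 = _aic_bic(rss2, n, two.n_params)
    preferred = ("two_component"
                 if (p_value < P_THRESHOLD and aic2 < aic1 and bic2 < bic1)
                 else "one_component")
    return ModelComparison(f_stat=float(f_stat), df_num=df_num,
                           df_den=df_den, p_value=p_value,
                           aic_one=float(aic1), aic_two=float(aic2),
                           bic_one=float(bic1), bic_two=float(bic2),
                           preferred=preferred)


def grid_search_rss(ecdf: EmpiricalCDF, forced_mean: float,
                    n_grid: int = 100, n_profile: int = 25,
                    n_polish: int = 5) -> float:
    """Brute-force residual sum of squares for the forced two-component
    model: exhaustive grid over (A3, A5) with (A2, A4) profiled.

    Diagnostic cross-check for the constrained optimizer, deliberately
    sharing no code with it: the rss over the grid is evaluated in closed
    form from precomputed component CDF tables, and the best ``n_polish``
    cells are refined by a local 2-parameter (A2, A4) minimisation.
    Returns the smallest rss found.
    """
    x, p = ecdf.values, ecdf.probs
    sd = float(np.std(x, ddof=1))
    a3_grid = np.linspace(float(x.min()), float(x.max()), n_grid)
    a5_grid = np.linspace(0.0, 1.0, n_grid)
    sd_grid = sd * np.logspace(-1.5, 0.7, n_profile)

    phi1 = np.stack([normal_cdf(x, forced_mean, s) for s in sd_grid])
    phi2 = np.stack([[normal_cdf(x, a3, s) for s in sd_grid]
                     for a3 in a3_grid])          # (n_grid, n_profile, n)
    s11 = np.einsum("an,an->a", phi1, phi1)
    s22 = np.einsum("ijn,ijn->ij", phi2, phi2)
    s12 = np.einsum("an,ijn->aij", phi1, phi2)
    t1 = phi1 @ p
    t2 = phi2 @ p
    pp = float(p @ p)

    best = []
    for a5 in a5_grid:
        w0, w1 = 1.0 - a5, a5
        rss = (w0 * w0 * s11[:, None, None] + 2 * w0 * w1 * s12
               + w1 * w1 * s22[None, :, :]
               - 2 * w0 * t1[:, None, None] - 2 * w1 * t2[None, :, :] + pp)
        flat = int(np.argmin(rss))
        i2, i3, i4 = np.unravel_index(flat, rss.shape)
        best.append((float(rss[i2, i3, i4]), float(a5),
                     float(sd_grid[i2]), float(a3_grid[i3]),
                     float(sd_grid[i4])))
    best.sort()
    best_rss = best[0][0]
    for rss0, a5, a2, a3, a4 in best[:n_polish]:
        def residuals(theta, a3=a3, a5=a5):
            return two_component_cdf(x, forced_mean, theta[0], a3,
                                     theta[1], a5) - p
        res = optimize.least_squares(
            residuals, np.array([a2, a4]),
            bounds=([_SD_FLOOR, _SD_FLOOR], [np.inf, np.inf]),
            ftol=_FTOL, max_nfev=200)
        best_rss = min(best_rss, float(res.cost * 2.0))
    return best_rss


def sharing_fraction(query_value: float, group_values: Sequence[float],
                     rule: SharingRule) -> float:
    """Fraction of the group's values inside the rule's interval around the
    query value (closed interval)."""
    g = np.asarray(group_values, dtype=float).ravel()
    if g.size == 0:
        raise DataError("sharing fraction needs a nonempty group")
    if not np.isfinite(query_value):
        raise DataError("query value must be finite")
    lo, hi = rule.interval(float(query_value))
    return float(np.mean((g >= lo) & (g <= hi)))
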