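"""Change-point detection for short, unevenly spaced proxy time series.

Two procedures are provided:

* CumSum: the cumulative sum of deviations from the series mean; slope-sign
  changes of the curve mark regime shifts.  Significance is formalized by
  requiring a minimum number of supporting points on each flank and a
  minimum slope change relative to the curve's overall gradient.

* GAM: a penalized cubic regression spline trend (smoothing parameter by
  GCV or REML); periods of significant change are grid intervals where the
  simultaneous confidence band on the first derivative excludes zero.  The
  band uses the max-|t| statistic over posterior coefficient draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from limnoflux.errors import (
    DataError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "ChangePointResult",
    "GamFit",
    "cumsum_curve",
    "cumsum_changepoints",
    "fit_gam_trend",
    "derivative_changepoints",
]

logger = logging.getLogger(__name__)


@dataclass
class ChangePointResult:
    """Detected change points with their supporting evidence.

    ``cp_times`` are calendar years; for the cumsum method ``detail`` rows
    carry flank slopes, sign change and supporting point counts, for the gam
    method ``intervals`` holds (t_start, t_end, derivative sign).
    """

    method: str
    cp_times: np.ndarray
    signs: np.ndarray
    intervals: list[tuple[float, float, int]] = field(default_factory=list)
    detail: list[dict] = field(default_factory=list)

    @property
    def principal_cp(self) -> float | None:
        """CP with the largest supporting statistic (None if none found)."""
        if len(self.detail) == 0:
            return None
        stats = [d.get("statistic", 0.0) for d in self.detail]
        return float(self.cp_times[int(np.argmax(stats))])


# ---------------------------------------------------------------------------
# CumSum


def cumsum_curve(values) -> np.ndarray:
    """Cumulative sum of deviations from the mean; final element is ~0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("cumsum needs >= 2 points")
    if np.any(~np.isfinite(x)):
        raise DataError("cumsum input contains non-finite values")
    return np.cumsum(x - x.mean())


def cumsum_changepoints(
    curve,
    times,
    min_segment: int = 5,
    slope_delta_min: float = 0.1,
) -> ChangePointResult:
    """Slope-sign-change CPs of a CumSum curve.

    A local extremum of the curve is reported as a CP when both flanking
    monotone segments contain at least ``min_segment`` points and the
    least-squares slope change across the extremum exceeds
    ``slope_delta_min * (curve range / time span)``.
    """
    if min_segment < 3:
        raise ParameterError("min_segment must be >= 3")
    c = np.asarray(curve, dtype=float)
    t = np.asarray(times, dtype=float)
    if c.shape != t.shape:
        raise ParameterError("curve and times differ in length")
    if c.size < 2 * min_segment:
        raise InsufficientDataError(
            f"series of {c.size} points is shorter than 2*min_segment"
        )
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")

    crange = float(np.ptp(c))
    span = float(t[-1] - t[0])
    if crange == 0:  # constant input: valid, no change points
        return ChangePointResult("cumsum", np.array([]), np.array([]))
    threshold = slope_delta_min * crange / span

    d = np.diff(c)
    sign = np.sign(d)
    # slope-sign flips that dominate their +/- min_segment neighbourhood
    # (plain sign flips are too fragile on noisy curves)
    ext = []
    for k in range(1, c.size - 1):
        if sign[k - 1] * sign[k] >= 0:
            continue
        lo = max(0, k - min_segment)
        hi = min(c.size, k + min_segment + 1)
        window = c[lo:hi]
        if c[k] == window.max() or c[k] == window.min():
            ext.append(k)

    seg_bounds = [0] + ext + [c.size - 1]
    cps, signs, detail = [], [], []
    for j, k in enumerate(ext):
        left = slice(seg_bounds[j], k + 1)
        right = slice(k, seg_bounds[j + 2] + 1)
        n_left = left.stop - left.start
        n_right = right.stop - right.start
        if n_left < min_segment or n_right < min_segment:
            continue
        slope_l = np.polyfit(t[left], c[left], 1)[0]
        slope_r = np.polyfit(t[right], c[right], 1)[0]
        delta = slope_r - slope_l
        if abs(delta) <= threshold:
            continue
        cp_time = 0.5 * (t[k] + t[k + 1])
        cps.append(cp_time)
        signs.append(int(np.sign(delta)))
        detail.append(
            {
                "cp_time": cp_time,
                "slope_before": float(slope_l),
                "slope_after": float(slope_r),
                "sign_change": "-to+" if delta > 0 else "+to-",
                "n_before": int(n_left),
                "n_after": int(n_right),
                "statistic": float(abs(delta) / (crange / span)),
            }
        )
    return ChangePointResult("cumsum", np.array(cps), np.array(signs), detail=detail)


# ---------------------------------------------------------------------------
# GAM trend


@dataclass
class GamFit:
    """Penalized cubic regression spline fit on time."""

    times: np.ndarray
    values: np.ndarray
    knots: np.ndarray
    degree: int
    coef: np.ndarray
    cov: np.ndarray  # Bayesian covariance of coef given the chosen smoothing
    fitted: np.ndarray
    scale: float  # residual variance estimate
    lam: float
    edf: float
    gcv: float
    method: str = "gcv"

    def design(self, t) -> np.ndarray:
        return _design(t, self.knots, self.degree)

    def predict(self, t) -> np.ndarray:
        return self.design(t) @ self.coef


def _design(t, knots: np.ndarray, degree: int) -> np.ndarray:
    """Basis evaluation with values clipped into the knots' base interval."""
    lo = np.nextafter(knots[degree], np.inf)
    hi = np.nextafter(knots[-degree - 1], -np.inf)
    t = np.clip(np.asarray(t, dtype=float), lo, hi)
    return BSpline.design_matrix(t, knots, degree).toarray()


def _spline_knots(t0: float, t1: float, n_basis: int, degree: int = 3) -> np.ndarray:
    # uniform knots extended past the span (P-spline construction): Greville
    # points are then evenly spaced, so the second-difference penalty's null
    # space is exactly the straight lines
    m = n_basis - degree
    h = (t1 - t0) / m
    return t0 + h * np.arange(-degree, m + degree + 1)


def fit_gam_trend(
    times,
    values,
    basis_dim: int = 10,
    method: str = "gcv",
    lam_grid: np.ndarray | None = None,
) -> GamFit:
    """Penalized-spline trend with smoothing chosen by GCV (or REML).

    The basis is a cubic B-spline with ``basis_dim`` functions on evenly
    spaced knots; the penalty is the squared second difference of the
    coefficients, so the infinite-smoothing limit is a straight line
    (effective degrees of freedom -> 2).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ParameterError("times and values must be matching 1-D arrays")
    n = t.size
    if n < 10:
        raise InsufficientDataError("GAM needs >= 10 points")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.any(np.diff(t) == 0):
        raise DataError("duplicate time values")
    if basis_dim >= n:
        new_dim = max(n // 2, 5)
        logger.info("basis_dim %d >= n %d; reduced to %d", basis_dim, n, new_dim)
        basis_dim = new_dim
    basis_dim = max(basis_dim, 5)

    degree = 3
    knots = _spline_knots(t[0], t[-1], basis_dim, degree)
    X = _design(t, knots, degree)
    D = np.diff(np.eye(basis_dim), n=2, axis=0)
    S = D.T @ D
    XtX = X.T @ X
    Xty = X.T @ y

    # scale-free lambda grid anchored at tr(X'X)/tr(S)
    anchor = np.trace(XtX) / max(np.trace(S), 1e-12)
    if lam_grid is None:
        lam_grid = anchor * np.logspace(-6, 8, 57)

    best = None
    for lam in lam_grid:
        A = XtX + lam * S
        try:
            cf = cho_factor(A + 1e-10 * np.eye(basis_dim))
        except LinAlgError:
            continue
        beta = cho_solve(cf, Xty)
        # edf = tr(X (X'X + lam S)^-1 X')
        edf = float(np.sum(X * cho_solve(cf, X.T).T))
        resid = y - X @ beta
        rss = float(resid @ resid)
        denom = max(n - edf, 1e-6)
        if method == "gcv":
            score = n * rss / denom**2
        elif method == "reml":
            sig2 = rss / denom
            # Laplace-style restricted likelihood (up to constants)
            sign, logdet_a = np.linalg.slogdet(A)
            ev = np.linalg.eigvalsh(lam * S)
            logdet_s = float(np.sum(np.log(ev[ev > 1e-10 * max(ev.max(), 1e-300)])))
            score = (rss / sig2 + (n - edf) * np.log(sig2) + logdet_a - logdet_s) / 2
        else:
            raise ParameterError(f"unknown smoothing method {method!r}")
        # ties (e.g. exactly representable data, RSS ~ 0 for every lambda)
        # break toward heavier smoothing: the grid ascends in lambda
        if best is None or score < best[0] * (1 + 1e-9) + 1e-300:
            sig2 = rss / denom
            cov = sig2 * cho_solve(cf, np.eye(basis_dim))
            best = (score, lam, beta, cov, edf, sig2, X @ beta)

    if best is None:
        raise DataError("GAM design matrix is singular for every lambda")
    score, lam, beta, cov, edf, sig2, fitted = best
    return GamFit(
        t, y, knots, degree, beta, cov, fitted, sig2, float(lam), edf, float(score), method
    )


def derivative_changepoints(
    fit: GamFit,
    n_draws: int = 2000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    n_grid: int = 2001,
) -> ChangePointResult:
    """Periods where the simultaneous band on the trend derivative excludes 0.

    The first derivative is taken by central finite differences of the
    spline basis (step = time range / (n_grid - 1)); the simultaneous
    critical value is the ``level`` quantile of the max-|t| statistic over
    ``n_draws`` Gaussian coefficient draws from the fit covariance.
    """
    if n_draws < 1000:
        raise ParameterError("n_draws must be >= 1000")
    if not (0 < level < 1):
        raise ParameterError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t0, t1 = fit.times[0], fit.times[-1]
    grid = np.linspace(t0, t1, n_grid)
    h = (t1 - t0) / (n_grid - 1)
    Xd = (fit.design(grid + h) - fit.design(grid - h)) / (2 * h)
    # endpoint evaluations are clamped inside the span -> one-sided differences
    Xd[0] *= 2.0
    Xd[-1] *= 2.0

    deriv = Xd @ fit.coef
    var = np.einsum("ij,jk,ik->i", Xd, fit.cov, Xd)
    se = np.sqrt(np.maximum(var, 0))
    if np.any(se <= 0):
        cond = np.linalg.cond(fit.cov)
        raise DataError(
            f"degenerate derivative variance (covariance condition {cond:.3g})"
        )

    try:
        L = cholesky(fit.cov + 1e-12 * np.trace(fit.cov) * np.eye(fit.cov.shape[0]), lower=True)
    except LinAlgError as exc:
        cond = np.linalg.cond(fit.cov)
        raise DataError(f"singular coefficient covariance (condition {cond:.3g})") from exc
    Z = rng.standard_normal((n_draws, fit.cov.shape[0]))
    dev = (Z @ L.T) @ Xd.T  # draws x grid deviations of the derivative
    max_t = np.max(np.abs(dev) / se[None, :], axis=1)
    crit = float(np.quantile(max_t, level))

    lo = deriv - crit * se
    hi = deriv + crit * se
    mask = (lo > 0) | (hi < 0)

    intervals: list[tuple[float, float, int]] = []
    cps, signs, detail = [], [], []
    i = 0
    while i < n_grid:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_grid and mask[j + 1]:
            j += 1
        if j - i >= 2:  # runs shorter than 2 grid steps are numerical noise
            sgn = int(np.sign(deriv[i : j + 1].mean()))
            intervals.append((float(grid[i]), float(grid[j]), sgn))
            k = i + int(np.argmax(np.abs(deriv[i : j + 1])))
            cps.append(float(grid[k]))
            signs.append(sgn)
            detail.append(
                {
                    "t_start": float(grid[i]),
                    "t_end": float(grid[j]),
                    "sign": sgn,
                    "statistic": float(np.max(np.abs(deriv[i : j + 1]) / se[i : j + 1])),
                }
            )
        i = j + 1

    res = ChangePointResult("gam", np.array(cps), np.array(signs), intervals, detail)
    res.detail_extra = {"crit": crit, "se": se, "deriv": deriv, "grid": grid}
    return res


def ensemble_changepoint_times(
    ages: np.ndarray,
    values: np.ndarray,
    method: str = "cumsum",
    seed: int | np.random.SeedSequence | None = None,
    **kwargs,
) -> list[np.ndarray]:
    """Per-member change-point times: the CP-time distribution across an
    age ensemble (``ages``/``values`` are members x samples; a 1-D value
    vector is shared by all members)."""
    ages = np.atleast_2d(np.asarray(ages, dtype=float))
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = np.broadcast_to(values, ages.shape)
    rng = np.random.default_rng(seed)
    out = []
    for m in range(ages.shape[0]):
        order = np.argsort(ages[m])
        t, v = ages[m][order], values[m][order]
        try:
            if method == "cumsum":
                res = cumsum_changepoints(cumsum_curve(v), t, **kwargs)
            elif method == "gam":
                fit = fit_gam_trend(t, v, **kwargs)
                res = derivative_changepoints(fit, seed=rng.integers(2**32))
            else:
                raise ParameterError(f"unknown method {method!r}")
            out.append(res.cp_times)
        except (InsufficientDataError, DataError):
            out.append(np.array([]))
    return out
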