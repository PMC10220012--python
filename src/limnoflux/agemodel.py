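"""Bayesian age-depth modelling with gamma-autoregressive accumulation.

The model follows the familiar sediment-core parameterization: the core is
divided into equal-thickness sections; section accumulation values a_i
(yr/cm) follow a first-order gamma mixture

    a_1 ~ Gamma(shape, mean)
    a_i = w * a_{i-1} + (1 - w) * g_i,   g_i ~ Gamma(shape, mean)

with memory w ~ Beta(mean=memory_mean, strength=memory_strength).  Ages are
measured internally in years before core collection and increase with depth
by construction, so every posterior member is monotone.  Dated horizons enter
through a Student-t likelihood; radiocarbon dates are compared in 14C space
through the calibration curve (no pre-calibration inside the MCMC).

The sampler is Metropolis-within-Gibbs with proposal scales adapted during
burn-in toward a 20-45% acceptance rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from limnoflux.calibration import CalibrationCurve
from limnoflux.errors import DataError, ParameterError, RangeError

__all__ = [
    "AgeModelSettings",
    "AgeDepthEnsemble",
    "fit_age_model",
    "ensemble_ages_at",
    "sed_rate_ensemble",
    "validate_date_table",
]

DATE_TYPES = {"radiocarbon", "calendar", "pb210", "cs137", "event"}
#: date types whose `age` column is a calendar year CE
CALENDAR_TYPES = DATE_TYPES - {"radiocarbon"}


@dataclass(frozen=True)
class AgeModelSettings:
    """Sampler and prior configuration (all exposed; defaults mirror the
    documented defaults of the established Bayesian age-depth tool)."""

    section_thickness: float = 5.0  # cm
    acc_mean: float | None = None  # yr/cm; None -> rough slope of extreme dates
    acc_shape: float = 1.5
    memory_mean: float = 0.7
    memory_strength: float = 4.0
    t_df: float = 6.0
    n_iter: int = 60_000
    burn_in: int = 10_000
    n_members: int = 1_000
    collection_year: float = 2015.0
    #: depth intervals (top_cm, bottom_cm) collapsed before modelling
    excluded_intervals: tuple[tuple[float, float], ...] = ()
    #: top age (yr before collection) used only in dateless prior-sampling mode
    prior_top_age: float = 0.0

    def __post_init__(self) -> None:
        if self.section_thickness <= 0:
            raise ParameterError("section_thickness must be > 0")
        if self.acc_mean is not None and self.acc_mean <= 0:
            raise ParameterError("acc_mean must be > 0")
        if self.acc_shape <= 0 or self.memory_strength <= 0:
            raise ParameterError("shape/strength parameters must be > 0")
        if not (0 < self.memory_mean < 1):
            raise ParameterError("memory_mean must lie in (0, 1)")
        if self.burn_in >= self.n_iter:
            raise ParameterError("burn_in must be < n_iter")
        if self.n_members < 1:
            raise ParameterError("n_members must be >= 1")


@dataclass
class AgeDepthEnsemble:
    """Posterior ensemble of monotone age-depth functions.

    ``ages`` holds years before core collection, shape (members, depths).
    """

    depths: np.ndarray
    ages: np.ndarray
    collection_year: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.ages = np.atleast_2d(np.asarray(self.ages, dtype=float))
        if self.ages.shape[1] != self.depths.size:
            raise ParameterError("ages and depths shapes disagree")
        if np.any(np.diff(self.ages, axis=1) < -1e-9):
            raise DataError("ensemble contains a non-monotone member")

    @property
    def n_members(self) -> int:
        return self.ages.shape[0]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.depths[0]), float(self.depths[-1])

    def ages_at(self, depths) -> np.ndarray:
        """Member x depth matrix of ages (yr before collection)."""
        return ensemble_ages_at(self, depths)

    def ages_ce_at(self, depths) -> np.ndarray:
        return self.collection_year - self.ages_at(depths)

    def median_ages_at(self, depths) -> np.ndarray:
        return np.median(self.ages_at(depths), axis=0)

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.ages, [50, 2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "depth": self.depths,
                "age_median": q[0],
                "age_q2_5": q[1],
                "age_q97_5": q[2],
                "age_ce_median": self.collection_year - q[0],
                "age_ce_q2_5": self.collection_year - q[2],
                "age_ce_q97_5": self.collection_year - q[1],
            }
        )

    def to_wide(self) -> pd.DataFrame:
        """Wide table: depth rows x member columns (ages yr before collection)."""
        cols = {f"member_{m}": self.ages[m] for m in range(self.n_members)}
        return pd.DataFrame({"depth": self.depths, **cols})

    @classmethod
    def from_wide(cls, df: pd.DataFrame, collection_year: float) -> "AgeDepthEnsemble":
        members = [c for c in df.columns if c.startswith("member_")]
        return cls(
            df["depth"].to_numpy(float),
            df[members].to_numpy(float).T,
            collection_year,
        )


# ---------------------------------------------------------------------------
# date-table validation


def validate_date_table(dates: pd.DataFrame) -> pd.DataFrame:
    """Check the dated-horizon table and return a clean copy.

    Required columns: ``labID, age, error, depth, type``.  ``age`` is in
    14C yr for radiocarbon rows and calendar yr CE otherwise.  An optional
    boolean ``excluded`` column drops rows from the likelihood.
    """
    required = {"labID", "age", "error", "depth", "type"}
    missing = required - set(dates.columns)
    if missing:
        raise DataError(f"date table missing columns: {sorted(missing)}")
    out = dates.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    out["excluded"] = out["excluded"].fillna(False).astype(bool)
    bad_type = set(out["type"]) - DATE_TYPES
    if bad_type:
        raise DataError(f"unknown date types: {sorted(bad_type)}")
    if (out["error"] <= 0).any():
        raise DataError("date errors must be > 0")
    if (out["depth"] < 0).any():
        raise DataError("date depths must be >= 0")
    if len(out) == 0:
        raise DataError("date table is empty")
    return out


def _check_stratigraphy(depth, age_bc, err) -> None:
    """Raise if two calendar dates force an age reversal beyond 5 sigma."""
    order = np.argsort(depth)
    d, a, e = depth[order], age_bc[order], err[order]
    for i in range(len(d) - 1):
        for j in range(i + 1, len(d)):
            if d[j] <= d[i]:
                continue
            tol = 5.0 * math.hypot(e[i], e[j])
            if a[j] < a[i] - tol:
                raise DataError(
                    f"calendar dates at {d[i]:.1f} and {d[j]:.1f} cm imply an "
                    f"age reversal beyond 5 sigma ({a[i] - a[j]:.1f} yr)"
                )


# ---------------------------------------------------------------------------
# excluded-interval depth collapsing


def _collapse_map(intervals):
    """Return (orig_pts, coll_pts) describing the piecewise-linear collapse."""
    ivs = sorted((float(t), float(b)) for t, b in intervals)
    for t, b in ivs:
        if b <= t or t < 0:
            raise ParameterError(f"bad excluded interval ({t}, {b})")
    orig = [0.0]
    coll = [0.0]
    removed = 0.0
    eps = 1e-9
    for t, b in ivs:
        orig.extend([t, b])
        coll.extend([t - removed, t - removed + eps])
        removed += b - t
    return np.array(orig), np.array(coll), removed


def _collapse_depths(depths, intervals):
    if not intervals:
        return np.asarray(depths, dtype=float)
    orig, coll, removed = _collapse_map(intervals)
    d = np.asarray(depths, dtype=float)
    out = np.interp(d, orig, coll)
    beyond = d > orig[-1]
    out[beyond] = d[beyond] - removed + coll[-1] - (orig[-1] - removed)
    return out


# ---------------------------------------------------------------------------
# the sampler


class _Posterior:
    """Vectorized log-posterior pieces for one core."""

    def __init__(self, dates, curve, settings, n_sections, thickness):
        self.t_df = settings.t_df
        self.k = settings.acc_shape
        self.theta = settings.acc_mean / settings.acc_shape
        self.alpha = settings.memory_mean * settings.memory_strength
        self.beta = (1 - settings.memory_mean) * settings.memory_strength
        self._lgk = gammaln(self.k)
        self.curve = curve
        self.offset_1950 = settings.collection_year - 1950.0

        d = dates
        self.is_rc = (d["type"] == "radiocarbon").to_numpy()
        self.obs = np.where(
            self.is_rc,
            d["age"].to_numpy(float),
            settings.collection_year - d["age"].to_numpy(float),
        )
        self.err = d["error"].to_numpy(float)
        # fixed weights: modelled age at a date = t0 + W @ a
        depth_c = d["_depth_collapsed"].to_numpy(float)
        K = n_sections
        W = np.zeros((len(d), K))
        for i, dep in enumerate(depth_c):
            sec = min(int(dep // thickness), K - 1)
            W[i, :sec] = thickness
            W[i, sec] = dep - sec * thickness
        self.W = W

    def _gamma_logpdf(self, x):
        return (self.k - 1) * np.log(x) - x / self.theta - self.k * np.log(self.theta) - self._lgk

    def log_prior(self, a, w) -> float:
        if w <= 0 or w >= 1 or a[0] <= 0:
            return -np.inf
        g = (a[1:] - w * a[:-1]) / (1 - w)
        if np.any(g <= 0):
            return -np.inf
        lp = self._gamma_logpdf(a[0])
        lp += self._gamma_logpdf(g).sum() - (a.size - 1) * math.log(1 - w)
        lp += (self.alpha - 1) * math.log(w) + (self.beta - 1) * math.log(1 - w)
        return float(lp)

    def log_lik(self, t0, a) -> float:
        md = t0 + self.W @ a  # modelled ages, yr before collection
        ll = 0.0
        df = self.t_df
        cal = ~self.is_rc
        if cal.any():
            z = (md[cal] - self.obs[cal]) / self.err[cal]
            ll += float(np.sum(-(df + 1) / 2 * np.log1p(z * z / df) - np.log(self.err[cal])))
        if self.is_rc.any():
            cal_bp = md[self.is_rc] - self.offset_1950
            lo, hi = self.curve.span
            if np.any(cal_bp < lo) or np.any(cal_bp > hi):
                return -np.inf
            mu = self.curve.c14_at(cal_bp)
            sc = np.sqrt(self.err[self.is_rc] ** 2 + self.curve.error_at(cal_bp) ** 2)
            z = (self.obs[self.is_rc] - mu) / sc
            ll += float(np.sum(-(df + 1) / 2 * np.log1p(z * z / df) - np.log(sc)))
        return ll


def _prior_ensemble(settings, n_sections, rng):
    """Direct draws from the accumulation prior (dateless mode)."""
    M = settings.n_members
    k, theta = settings.acc_shape, settings.acc_mean / settings.acc_shape
    w = rng.beta(
        settings.memory_mean * settings.memory_strength,
        (1 - settings.memory_mean) * settings.memory_strength,
        size=M,
    )
    a = np.empty((M, n_sections))
    a[:, 0] = rng.gamma(k, theta, size=M)
    for i in range(1, n_sections):
        g = rng.gamma(k, theta, size=M)
        a[:, i] = w * a[:, i - 1] + (1 - w) * g
    ages = settings.prior_top_age + np.concatenate(
        [np.zeros((M, 1)), np.cumsum(a * settings.section_thickness, axis=1)], axis=1
    )
    return ages, {"mode": "prior", "mean_acc": float(a.mean())}


def _init_state(post, dates, settings, curve, n_sections):
    """Least-squares initialization from the observed dates."""
    depth = dates["_depth_collapsed"].to_numpy(float)
    age_bc = np.empty(len(dates))
    for i, (_, row) in enumerate(dates.iterrows()):
        if row["type"] == "radiocarbon":
            j = int(np.argmin(np.abs(curve.c14_age - row["age"])))
            age_bc[i] = curve.cal_bp[j] + (settings.collection_year - 1950.0)
        else:
            age_bc[i] = settings.collection_year - row["age"]
    if len(dates) >= 2 and np.ptp(depth) > 0:
        slope, intercept = np.polyfit(depth, age_bc, 1)
    else:
        slope, intercept = settings.acc_mean, age_bc[0] - settings.acc_mean * depth[0]
    slope = max(slope, 0.05 * settings.acc_mean)
    a0 = np.full(n_sections, slope)
    t0 = float(intercept)
    return t0, a0, settings.memory_mean, float(np.median(age_bc))


def _rough_acc_mean(dates, settings, curve):
    """Default acc_mean: span slope from the extreme dates, 1 significant figure."""
    depth = dates["_depth_collapsed"].to_numpy(float)
    age_bc = np.empty(len(dates))
    for i, (_, row) in enumerate(dates.iterrows()):
        if row["type"] == "radiocarbon":
            j = int(np.argmin(np.abs(curve.c14_age - row["age"])))
            age_bc[i] = curve.cal_bp[j] + (settings.collection_year - 1950.0)
        else:
            age_bc[i] = settings.collection_year - row["age"]
    i_top, i_bot = int(np.argmin(depth)), int(np.argmax(depth))
    dd = depth[i_bot] - depth[i_top]
    slope = (age_bc[i_bot] - age_bc[i_top]) / dd if dd > 0 else 0.0
    if slope <= 0:
        return 10.0
    exp10 = math.floor(math.log10(slope))
    return round(slope / 10**exp10) * 10**exp10


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction of one scalar trace."""
    n = x.size // 2 * 2
    if n < 4:
        return float("nan")
    halves = x[:n].reshape(2, -1)
    W = halves.var(axis=1, ddof=1).mean()
    B = halves.shape[1] * halves.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (halves.shape[1] - 1) / halves.shape[1] * W + B / halves.shape[1]
    return float(np.sqrt(var_plus / W))


def fit_age_model(
    dates: pd.DataFrame | None,
    curve: CalibrationCurve | None = None,
    *,
    core_depth: float | None = None,
    settings: AgeModelSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> AgeDepthEnsemble:
    """Fit the Bayesian age-depth model and return a thinned posterior ensemble.

    Parameters
    ----------
    dates
        Dated-horizon table (see :func:`validate_date_table`); ``None`` or an
        all-excluded table triggers prior-sampling mode.
    curve
        Calibration curve; required when radiocarbon dates are present.
    core_depth
        Bottom depth to model, cm; defaults to the deepest date (or one
        section in dateless mode).
    """
    settings = settings or AgeModelSettings()
    rng = np.random.default_rng(seed)

    active = None
    if dates is not None and len(dates):
        dates = validate_date_table(dates)
        active = dates.loc[~dates["excluded"]].reset_index(drop=True)
        if len(active) == 0:
            active = None

    if active is not None and (active["type"] == "radiocarbon").any() and curve is None:
        raise ParameterError("radiocarbon dates require a calibration curve")
    curve = curve or CalibrationCurve.identity()

    if core_depth is None:
        core_depth = float(active["depth"].max()) if active is not None else settings.section_thickness
    if active is not None and core_depth < active["depth"].max():
        raise RangeError("core_depth does not cover all dated depths")

    total_excluded = sum(b - t for t, b in settings.excluded_intervals)
    depth_span = core_depth - total_excluded
    n_sections = max(1, math.ceil(depth_span / settings.section_thickness - 1e-9))
    thickness = settings.section_thickness

    # boundaries in collapsed space; reported grid is re-expanded below
    coll_bounds = np.arange(n_sections + 1) * thickness

    if active is None:
        if settings.acc_mean is None:
            settings = replace(settings, acc_mean=10.0)
        ages, diag = _prior_ensemble(settings, n_sections, rng)
        grid = _expand_grid(coll_bounds, settings.excluded_intervals)
        return AgeDepthEnsemble(grid[0], ages[:, grid[1]], settings.collection_year, diag)

    active = active.copy()
    active["_depth_collapsed"] = _collapse_depths(
        active["depth"].to_numpy(float), settings.excluded_intervals
    )

    cal_mask = active["type"].isin(CALENDAR_TYPES).to_numpy()
    if cal_mask.sum() >= 2:
        _check_stratigraphy(
            active.loc[cal_mask, "_depth_collapsed"].to_numpy(float),
            settings.collection_year - active.loc[cal_mask, "age"].to_numpy(float),
            active.loc[cal_mask, "error"].to_numpy(float),
        )

    if settings.acc_mean is None:
        settings = replace(settings, acc_mean=_rough_acc_mean(active, settings, curve))

    post = _Posterior(active, curve, settings, n_sections, thickness)
    t0, a, w, _ = _init_state(post, active, settings, curve, n_sections)
    # nudge the init into the prior support
    lp = post.log_prior(a, w)
    if not np.isfinite(lp):
        a = np.full(n_sections, settings.acc_mean)
        lp = post.log_prior(a, w)
    ll = post.log_lik(t0, a)

    n_par = n_sections + 3  # t0, a_1..a_K, w, global accumulation scale
    scales = np.empty(n_par)
    scales[0] = max(2.0 * float(np.median(post.err)), 1.0)
    scales[1:-2] = 0.25
    scales[-2] = 0.6
    scales[-1] = 0.1
    acc_count = np.zeros(n_par)
    prop_count = np.zeros(n_par)

    n_iter, burn = settings.n_iter, settings.burn_in
    keep_idx = np.unique(np.linspace(burn, n_iter - 1, settings.n_members).astype(int))
    keep_set = set(keep_idx.tolist())
    kept = []
    scalar_trace = np.empty(n_iter - burn)

    for it in range(n_iter):
        # t0 (flat prior -> likelihood only)
        t0p = t0 + rng.normal(0.0, scales[0])
        llp = post.log_lik(t0p, a)
        prop_count[0] += 1
        if math.log(rng.random()) < llp - ll:
            t0, ll = t0p, llp
            acc_count[0] += 1
        # sections: multiplicative log-normal walk
        for i in range(n_sections):
            ap = a.copy()
            ap[i] = a[i] * math.exp(rng.normal(0.0, scales[1 + i]))
            lpp = post.log_prior(ap, w)
            prop_count[1 + i] += 1
            if np.isfinite(lpp):
                llp = post.log_lik(t0, ap)
                ratio = (lpp + llp + math.log(ap[i])) - (lp + ll + math.log(a[i]))
                if math.log(rng.random()) < ratio:
                    a, lp, ll = ap, lpp, llp
                    acc_count[1 + i] += 1
        # memory: logit walk
        lw = math.log(w / (1 - w)) + rng.normal(0.0, scales[-2])
        wp = 1.0 / (1.0 + math.exp(-lw))
        lpp = post.log_prior(a, wp)
        prop_count[-2] += 1
        if np.isfinite(lpp):
            ratio = (lpp + math.log(wp * (1 - wp))) - (lp + math.log(w * (1 - w)))
            if math.log(rng.random()) < ratio:
                w, lp = wp, lpp
                acc_count[-2] += 1
        # global multiplicative rescaling of all accumulations (mixing move)
        eps = rng.normal(0.0, scales[-1])
        ap = a * math.exp(eps)
        lpp = post.log_prior(ap, w)
        prop_count[-1] += 1
        if np.isfinite(lpp):
            llp = post.log_lik(t0, ap)
            ratio = (lpp + llp + n_sections * eps) - (lp + ll)
            if math.log(rng.random()) < ratio:
                a, lp, ll = ap, lpp, llp
                acc_count[-1] += 1

        if it < burn and (it + 1) % 50 == 0:
            rate = acc_count / np.maximum(prop_count, 1)
            scales *= np.exp(1.2 * (rate - 0.3))
            np.clip(scales, 1e-4, 50.0, out=scales)
            acc_count[:] = 0
            prop_count[:] = 0

        if it >= burn:
            scalar_trace[it - burn] = t0 + a.mean() * depth_span / 2
            if it in keep_set:
                kept.append(np.concatenate([[t0], t0 + np.cumsum(a) * thickness]))

    members = np.asarray(kept)

    rate = acc_count / np.maximum(prop_count, 1)
    rhat = _split_rhat(scalar_trace)
    diag = {
        "mode": "posterior",
        "acceptance": rate.tolist(),
        "rhat_mean_age": rhat,
        "convergence_warning": bool(np.isfinite(rhat) and rhat > 1.1),
        "acc_mean_used": settings.acc_mean,
        "n_sections": n_sections,
    }

    grid_depths, grid_cols = _expand_grid(coll_bounds, settings.excluded_intervals)
    return AgeDepthEnsemble(
        grid_depths, members[:, grid_cols], settings.collection_year, diag
    )


def _expand_grid(coll_bounds, intervals):
    """Map collapsed boundaries back to original depths.

    Returns (original_depths, column_index_into_collapsed_boundaries); an
    excluded interval appears as two grid points with equal ages
    (instantaneous deposition).
    """
    if not intervals:
        return coll_bounds.copy(), np.arange(coll_bounds.size)
    orig, coll, removed = _collapse_map(intervals)
    depths = []
    cols = []
    for j, cb in enumerate(coll_bounds):
        d = float(np.interp(cb, coll, orig))
        if cb > coll[-1]:
            d = cb + removed
        depths.append(d)
        cols.append(j)
        # insert the interval bottom right after its (collapsed) top
        for (t, b) in sorted(intervals):
            ct = _collapse_depths([t], intervals)[0]
            if abs(cb - ct) < 1e-6:
                depths.append(b)
                cols.append(j)
    depths = np.array(depths)
    cols = np.array(cols)
    order = np.argsort(depths, kind="stable")
    return depths[order], cols[order]


# ---------------------------------------------------------------------------
# ensemble queries


def ensemble_ages_at(ens: AgeDepthEnsemble, depths) -> np.ndarray:
    """Piecewise-linear interpolation of every member at the given depths."""
    d = np.atleast_1d(np.asarray(depths, dtype=float))
    lo, hi = ens.span
    if np.any(d < lo - 1e-9) or np.any(d > hi + 1e-9):
        raise RangeError(f"depths outside modelled span [{lo}, {hi}] cm")
    d = np.clip(d, lo, hi)
    grid = ens.depths
    idx = np.clip(np.searchsorted(grid, d, side="right") - 1, 0, grid.size - 2)
    width = grid[idx + 1] - grid[idx]
    frac = np.where(width > 0, (d - grid[idx]) / np.where(width > 0, width, 1.0), 0.0)
    left = ens.ages[:, idx]
    right = ens.ages[:, idx + 1]
    return left + frac[None, :] * (right - left)


def sed_rate_ensemble(ens: AgeDepthEnsemble, depths) -> np.ndarray:
    """Member x interval sedimentation rates (cm/yr) between successive depths."""
    d = np.asarray(depths, dtype=float)
    if d.size < 2:
        raise ParameterError("need >= 2 depths for sedimentation rates")
    if np.any(np.diff(d) <= 0):
        raise ParameterError("depths must be strictly increasing")
    ages = ensemble_ages_at(ens, d)
    dt = np.diff(ages, axis=1)
    if np.any(dt <= 0):
        raise DataError("zero age increment over a depth interval (degenerate)")
    return np.diff(d)[None, :] / dt
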