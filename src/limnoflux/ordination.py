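"""Ordination: compositional, Hellinger-diatom and age-uncertain PCA.

Three PCA paths share a result container:

* :func:`standardized_pca` -- centred (optionally unit-variance) SVD.
* :func:`hellinger_pca` -- square-root relative-abundance transform of
  filtered diatom counts, then centred PCA.
* :func:`ppca_missing` -- probabilistic PCA (latent factors + isotropic
  noise) fitted by EM with missing cells integrated out.

:func:`age_uncertain_pca` propagates chronological uncertainty by binning
every series onto a common time grid per age-ensemble member, running PPCA
per member, sign-aligning components to a reference member and summarizing
scores with highest-density bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from limnoflux.errors import (
    ConvergenceError,
    CoverageError,
    DataError,
    ParameterError,
)
from limnoflux.flux import bin_ensemble_series

__all__ = [
    "PCAResult",
    "EnsemblePCAResult",
    "AgeUncertainSeries",
    "standardized_pca",
    "hellinger_pca",
    "hellinger_transform",
    "ppca_missing",
    "age_uncertain_pca",
    "diatom_summaries",
    "hdr_interval",
]

logger = logging.getLogger(__name__)

#: columns of a diatom count table that are not taxa
RESERVED_DIATOM_COLUMNS = {
    "depth",
    "age_ce",
    "cysts",
    "microspheres",
    "spike",
    "mass_g",
}


@dataclass
class PCAResult:
    """Loadings (variable x component, unit-norm columns), scores and
    variance fractions (non-increasing, summing to <= 1)."""

    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    variables: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, dtype=float)
        if np.any(vf < -1e-12) or vf.sum() > 1 + 1e-9:
            raise DataError("variance fractions must lie in [0,1] and sum <= 1")
        if np.any(np.diff(vf) > 1e-9):
            raise DataError("variance fractions must be non-increasing")


def _svd_flip(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Deterministic sign: largest-|loading| entry of each component positive."""
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            if scores is not None:
                scores[:, k] = -scores[:, k]
    return loadings, scores


def standardized_pca(
    matrix,
    standardize: bool = True,
    variables: list[str] | None = None,
) -> PCAResult:
    """Column-centred (and optionally unit-variance) PCA by SVD."""
    X = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
        X = matrix.to_numpy(float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ParameterError("need a 2-D matrix with >= 2 samples and >= 2 variables")
    if np.any(~np.isfinite(X)):
        raise DataError("matrix contains missing values; use ppca_missing")
    if variables is None:
        variables = [f"v{j}" for j in range(X.shape[1])]

    sd = X.std(axis=0, ddof=1)
    if standardize:
        # tolerance absorbs float round-off in constant columns
        keep = sd > 1e-12 * (np.abs(X.mean(axis=0)) + 1.0)
        if not keep.all():
            dropped = [v for v, k in zip(variables, keep) if not k]
            logger.info("excluding zero-variance columns: %s", dropped)
            X = X[:, keep]
            variables = [v for v, k in zip(variables, keep) if k]
            sd = sd[keep]
            if X.shape[1] < 2:
                raise DataError("fewer than 2 non-constant variables remain")
        Xc = (X - X.mean(axis=0)) / sd
    else:
        Xc = X - X.mean(axis=0)

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    scores = U * s
    total = float(np.sum(s**2))
    vf = s**2 / total if total > 0 else np.zeros_like(s)
    loadings, scores = _svd_flip(loadings, scores)
    return PCAResult(loadings, scores, vf, variables, {"standardize": standardize})


# ---------------------------------------------------------------------------
# Hellinger diatom PCA


def _taxon_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c not in RESERVED_DIATOM_COLUMNS]


def hellinger_transform(counts: np.ndarray) -> np.ndarray:
    """sqrt of relative abundances; each row has unit sum of squares."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DataError("every sample must have a positive valve total")
    return np.sqrt(counts / totals)


def filter_taxa(
    counts: pd.DataFrame,
    min_abundance: float = 0.01,
    min_occurrences: int = 2,
) -> list[str]:
    """Taxa whose maximum relative abundance exceeds ``min_abundance`` and
    that occur (count > 0) in at least ``min_occurrences`` samples."""
    taxa = _taxon_columns(counts)
    mat = counts[taxa].to_numpy(float)
    totals = mat.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DataError("sample with zero diatom valves")
    rel = mat / totals
    keep = (rel.max(axis=0) > min_abundance) & ((mat > 0).sum(axis=0) >= min_occurrences)
    return [t for t, k in zip(taxa, keep) if k]





def hellinger_pca(
    counts: pd.DataFrame,
    min_abundance: float = 0.01,
    min_occurrences: int = 2,
) -> PCAResult:
    """Centred PCA of Hellinger-transformed, abundance-filtered diatom counts."""
    kept = filter_taxa(counts, min_abundance, min_occurrences)
    if not kept:
        raise DataError("abundance filter removed every taxon")
    H = hellinger_transform(counts[kept].to_numpy(float))
    res = standardized_pca(H, standardize=False, variables=kept)
    res.meta.update(
        {"transform": "hellinger", "min_abundance": min_abundance,
         "min_occurrences": min_occurrences, "n_taxa_in": len(_taxon_columns(counts))}
    )
    return res


# ---------------------------------------------------------------------------
# probabilistic PCA with missing data


def ppca_missing(
    matrix,
    n_components: int = 2,
    tol: float = 1e-7,
    max_iter: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
) -> PCAResult:
    """EM for probabilistic PCA; NaN cells are integrated out.

    After convergence the factor matrix is rotated to orthonormal principal
    axes; scores are projections of the EM-completed matrix and variance
    fractions are score variances over the completed matrix's total
    variance, so with complete data the result coincides with classical PCA.
    """
    X = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(float)
    if X.ndim != 2:
        raise ParameterError("matrix must be 2-D")
    n, p = X.shape
    obs = np.isfinite(X)
    if np.any(~obs.any(axis=1)):
        raise DataError("a row has no observed cells")
    if np.any(~obs.any(axis=0)):
        raise DataError("a column has no observed cells")
    q = min(n_components, p, n - 1)
    if q < 1:
        raise ParameterError("n_components must be >= 1")

    rng = np.random.default_rng(seed)
    mu = np.array([X[obs[:, j], j].mean() for j in range(p)])
    col_var = np.array([X[obs[:, j], j].var() if obs[:, j].sum() > 1 else 1.0 for j in range(p)])
    W = rng.standard_normal((p, q)) * 0.1 * np.sqrt(max(col_var.mean(), 1e-12))
    sigma2 = max(0.5 * float(col_var.mean()), 1e-12)

    Xc = np.where(obs, X - mu, 0.0)
    ll_old = -np.inf
    last_delta = np.inf
    converged = False
    Iq = np.eye(q)

    # group rows by missing pattern so E-step matrices are shared
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    for it in range(max_iter):
        Ez = np.zeros((n, q))
        Ezz_sum_per_var = np.zeros((p, q, q))
        ll = 0.0
        Minv_per_row = np.zeros((n, q, q))
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            Wo = W[o]
            M = Wo.T @ Wo + sigma2 * Iq
            Minv = np.linalg.inv(M)
            idx = np.array(rows)
            Xo = Xc[np.ix_(idx, np.where(o)[0])]
            Ez[idx] = Xo @ Wo @ Minv
            Minv_per_row[idx] = Minv
            # observed-data log-likelihood via Woodbury/determinant lemma
            d_o = int(o.sum())
            sign, logdet_m = np.linalg.slogdet(M)
            logdet_c = (d_o - q) * np.log(sigma2) + logdet_m
            # tr(C^-1 S) summed over rows of this pattern
            XW = Xo @ Wo
            quad = (Xo**2).sum() / sigma2 - np.einsum(
                "ij,jk,ik->", XW, Minv, XW
            ) / sigma2
            ll += -0.5 * (
                len(rows) * (d_o * np.log(2 * np.pi) + logdet_c) + quad
            )

        # M-step (per-variable, rows where that variable is observed)
        W_new = np.zeros_like(W)
        for j in range(p):
            rows = obs[:, j]
            Ez_j = Ez[rows]
            G = Ez_j.T @ Ez_j + sigma2 * Minv_per_row[rows].sum(axis=0)
            b = Ez_j.T @ Xc[rows, j]
            W_new[j] = np.linalg.solve(G, b)
            Ezz_sum_per_var[j] = G
        mu_new = mu + np.array(
            [
                (Xc[obs[:, j], j] - Ez[obs[:, j]] @ W_new[j]).mean()
                for j in range(p)
            ]
        )
        # recentre before the sigma2 update
        shift = mu_new - mu
        Xc = np.where(obs, X - mu_new, 0.0)
        mu = mu_new

        num = 0.0
        n_obs_total = int(obs.sum())
        for j in range(p):
            rows = obs[:, j]
            resid = Xc[rows, j] - Ez[rows] @ W_new[j]
            num += float(resid @ resid)
            num += sigma2 * float(
                np.einsum("k,rkl,l->", W_new[j], Minv_per_row[rows], W_new[j])
            )
        sigma2 = max(num / n_obs_total, 1e-12)
        W = W_new

        if it > 0:
            last_delta = abs(ll - ll_old) / (abs(ll_old) + 1e-12)
            if last_delta <= tol:
                converged = True
                break
        ll_old = ll

    if not converged and max_iter > 1:
        raise ConvergenceError(
            f"PPCA EM did not converge in {max_iter} iterations "
            f"(last relative log-likelihood change {last_delta:.3g})"
        )

    # rotate to orthonormal principal axes and complete the matrix
    X_complete = np.where(obs, X, mu + Ez @ W.T)
    Xc_full = X_complete - X_complete.mean(axis=0)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    # order axes by projected variance of the completed data
    proj = Xc_full @ U
    var_k = proj.var(axis=0, ddof=1)
    order = np.argsort(var_k)[::-1]
    axes = U[:, order]
    scores = Xc_full @ axes
    total_var = float(Xc_full.var(axis=0, ddof=1).sum())
    vf = scores.var(axis=0, ddof=1) / total_var if total_var > 0 else np.zeros(q)
    axes = axes.copy()
    axes, scores = _svd_flip(axes, scores)
    return PCAResult(
        axes,
        scores,
        vf,
        meta={"sigma2": sigma2, "n_iter": it + 1, "loglik": ll, "completed": X_complete},
    )


# ---------------------------------------------------------------------------
# age-uncertain PCA


@dataclass
class AgeUncertainSeries:
    """One down-core variable with an ensemble of sample ages.

    ``ages_ce`` is (members, samples); ``values`` is (samples,) for proxies
    measured on depth, or (members, samples) for flux-like quantities that
    themselves vary across the chronology ensemble.
    """

    name: str
    ages_ce: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ages_ce = np.atleast_2d(np.asarray(self.ages_ce, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            if self.values.size != self.ages_ce.shape[1]:
                raise ParameterError(f"series {self.name}: values/ages length mismatch")
        elif self.values.shape != self.ages_ce.shape:
            raise ParameterError(f"series {self.name}: values/ages shape mismatch")

    @property
    def n_members(self) -> int:
        return self.ages_ce.shape[0]

    def member(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        vals = self.values if self.values.ndim == 1 else self.values[m]
        return self.ages_ce[m], vals


@dataclass
class EnsemblePCAResult:
    """Per-member PCA of binned, standardized age-uncertain series."""

    bin_centres: np.ndarray
    scores: np.ndarray  # (members, bins, components), NaN where bin unused
    loadings: np.ndarray  # (members, variables, components)
    variance_fractions: np.ndarray  # (members, components)
    variables: list[str]
    score_median: np.ndarray = field(init=False)
    hdr50: np.ndarray = field(init=False)  # (bins, components, 2)
    hdr95: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m, b, q = self.scores.shape
        self.score_median = np.full((b, q), np.nan)
        self.hdr50 = np.full((b, q, 2), np.nan)
        self.hdr95 = np.full((b, q, 2), np.nan)
        for k in range(q):
            for i in range(b):
                x = self.scores[:, i, k]
                x = x[np.isfinite(x)]
                if x.size == 0:
                    continue
                self.score_median[i, k] = np.median(x)
                lo50, hi50 = hdr_interval(x, 0.50)
                lo95, hi95 = hdr_interval(x, 0.95)
                # enforce band nesting
                self.hdr50[i, k] = (lo50, hi50)
                self.hdr95[i, k] = (min(lo95, lo50), max(hi95, hi50))

    def band_table(self, component: int = 0) -> pd.DataFrame:
        k = component
        return pd.DataFrame(
            {
                "bin_centre": self.bin_centres,
                "median": self.score_median[:, k],
                "hdi50_lo": self.hdr50[:, k, 0],
                "hdi50_hi": self.hdr50[:, k, 1],
                "hdi95_lo": self.hdr95[:, k, 0],
                "hdi95_hi": self.hdr95[:, k, 1],
            }
        )


def hdr_interval(x: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sample values."""
    if not (0 < mass <= 1):
        raise ParameterError("mass must lie in (0, 1]")
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n == 0:
        raise ParameterError("empty sample")
    w = max(int(np.ceil(mass * n)), 1)
    if w >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[w:] - xs[: n - w]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + w])


def age_uncertain_pca(
    series_set: list[AgeUncertainSeries],
    bin_width: float = 25.0,
    t0: float = 800.0,
    t1: float = 2015.0,
    n_members_used: int | None = None,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    max_empty_fraction: float = 0.5,
) -> EnsemblePCAResult:
    """Binned, per-member probabilistic PCA across age-uncertain series.

    For each ensemble draw every series is averaged onto the common
    ``bin_width`` grid, standardized, and the resulting bins x variables
    matrix (empty bins missing) is decomposed with :func:`ppca_missing`.
    Component signs are aligned to the first member's loadings.
    """
    if len(series_set) < 1:
        raise ParameterError("need at least one series")
    M_avail = min(s.n_members for s in series_set)
    M = M_avail if n_members_used is None else min(n_members_used, M_avail)
    if n_members_used is not None and M_avail < n_members_used:
        logger.info("only %d members available (requested %d)", M_avail, n_members_used)
    rng = np.random.default_rng(seed)

    names = [s.name for s in series_set]
    p = len(series_set)

    # bin all members of all series once
    binned = []  # per series: (bins, members)
    centres = None
    for s in series_set:
        c, mat, _ = bin_ensemble_series(
            s.ages_ce[:M],
            s.values if s.values.ndim == 1 else s.values[:M],
            bin_width,
            t0,
            t1,
        )
        centres = c
        binned.append(mat)

    stack = np.stack(binned, axis=-1)  # (bins, members, variables)
    empty_frac = float(np.mean(~np.isfinite(stack)))
    if empty_frac > max_empty_fraction:
        raise CoverageError(
            f"{empty_frac:.0%} of (bin, member, variable) cells are empty "
            f"(limit {max_empty_fraction:.0%}); widen bins or the window"
        )

    n_bins = centres.size
    q = min(n_components, p)
    scores = np.full((M, n_bins, q), np.nan)
    loadings = np.full((M, p, q), np.nan)
    vfs = np.full((M, q), np.nan)
    ref_loadings = None

    for m in range(M):
        Xm = stack[:, m, :]  # bins x variables
        col_ok = np.isfinite(Xm).any(axis=0)
        if not col_ok.all():
            missing_vars = [names[j] for j in range(p) if not col_ok[j]]
            raise CoverageError(f"variables with no occupied bins: {missing_vars}")
        mean = np.nanmean(Xm, axis=0)
        sd = np.nanstd(Xm, axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (Xm - mean) / sd
        row_ok = np.isfinite(Z).any(axis=1)
        Zr = Z[row_ok]
        if Zr.shape[0] <= q:
            raise CoverageError("too few occupied bins for the requested components")
        res = ppca_missing(
            Zr, n_components=q, tol=tol, max_iter=max_iter, seed=rng.integers(2**32)
        )
        L = res.loadings
        S = res.scores
        if ref_loadings is None:
            ref_loadings = L.copy()
        else:
            for k in range(q):
                if np.dot(L[:, k], ref_loadings[:, k]) < 0:
                    L[:, k] = -L[:, k]
                    S[:, k] = -S[:, k]
        loadings[m] = L
        vfs[m] = res.variance_fractions
        scores[m, row_ok, :] = S

    return EnsemblePCAResult(centres, scores, loadings, vfs, names)


# ---------------------------------------------------------------------------
# diatom summaries


def diatom_summaries(
    counts: pd.DataFrame,
    planktonic: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample relative abundances plus derived summaries.

    Returns a frame with ``rel_<taxon>`` columns, the chrysophyte-cyst to
    diatom ratio ``cd_ratio``, ``planktonic_fraction`` (when a planktonic
    taxon list is given) and ``valves_per_g`` (when microsphere spike data
    are present).
    """
    taxa = _taxon_columns(counts)
    if not taxa:
        raise DataError("count table has no taxon columns")
    mat = counts[taxa].to_numpy(float)
    if np.any(mat < 0) or np.any(mat != np.floor(mat)):
        raise DataError("valve counts must be non-negative integers")
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        raise DataError("sample with zero diatom valves")
    rel = mat / totals[:, None]

    out = pd.DataFrame({f"rel_{t}": rel[:, j] for j, t in enumerate(taxa)})
    if "depth" in counts.columns:
        out.insert(0, "depth", counts["depth"].to_numpy(float))
    out["total_valves"] = totals

    if "cysts" in counts.columns:
        out["cd_ratio"] = counts["cysts"].to_numpy(float) / totals

    if planktonic is not None:
        unknown = set(planktonic) - set(taxa)
        if unknown:
            raise ParameterError(f"unknown planktonic taxa: {sorted(unknown)}")
        cols = [taxa.index(t) for t in planktonic]
        out["planktonic_fraction"] = rel[:, cols].sum(axis=1)

    if {"microspheres", "spike", "mass_g"} <= set(counts.columns):
        ms = counts["microspheres"].to_numpy(float)
        if np.any(ms <= 0):
            raise DataError("zero microspheres counted; concentration undefined")
        out["valves_per_g"] = (
            totals * counts["spike"].to_numpy(float) / ms / counts["mass_g"].to_numpy(float)
        )
    return out
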