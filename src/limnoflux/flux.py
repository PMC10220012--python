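"""Compositional closure and flux computation per age-ensemble member.

Fluxes follow the stoichiometric bookkeeping used for lake-sediment cores:

    %carbonates     = 100.09 * TIC / 12.01
    %organic matter = 1.724 * TOC          (Van Bemmelen factor)
    %silicates      = 100 - %carbonates - %organic matter

    TOC_flux = density * SR * %TOC/100 * 1e4       [g m-2 yr-1]
    L_flux   = density * SR * (100-%TOC-%TIC)/100 * 1e4

with density in g/cm3 and SR in cm/yr; the 1e4 factor converts
g cm-2 yr-1 to g m-2 yr-1.  The sedimentation rate attached to a sample is
the interval rate between neighbouring sample midpoints, evaluated per
ensemble member, so chronological uncertainty propagates into every flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from limnoflux.agemodel import AgeDepthEnsemble, ensemble_ages_at, sed_rate_ensemble
from limnoflux.errors import DataError, ParameterError

__all__ = [
    "CARBONATE_FACTOR",
    "VAN_BEMMELEN_FACTOR",
    "CompositionClosure",
    "FluxEnsemble",
    "composition_closure",
    "compute_fluxes",
    "trap_flux",
    "bin_flux_ensemble",
    "bin_ensemble_series",
]

#: CaCO3/C molar mass ratio, as printed for the carbonate closure
CARBONATE_FACTOR = 100.09 / 12.01
#: organic matter per unit organic carbon
VAN_BEMMELEN_FACTOR = 1.724


class ClosureWarning(UserWarning):
    """%carbonates + %organic matter exceeded 100 before clipping."""


@dataclass(frozen=True)
class CompositionClosure:
    """Three-component closure, % dry mass; sums to 100 where not clipped."""

    carbonates: np.ndarray
    organic_matter: np.ndarray
    silicates: np.ndarray
    clipped: np.ndarray  # True where silicate went negative before clipping


def composition_closure(
    toc, tic, om_factor: float = VAN_BEMMELEN_FACTOR
) -> CompositionClosure:
    """Closure of %carbonates / %organic matter / %silicates from TOC, TIC."""
    toc = np.atleast_1d(np.asarray(toc, dtype=float))
    tic = np.atleast_1d(np.asarray(tic, dtype=float))
    if np.any(toc < 0) or np.any(tic < 0):
        raise ParameterError("TOC and TIC must be >= 0")
    carb = CARBONATE_FACTOR * tic
    om = om_factor * toc
    sil_raw = 100.0 - carb - om
    clipped = sil_raw < 0
    if np.any(clipped):
        overshoot = float(np.max(-sil_raw[clipped]))
        warnings.warn(
            f"closure overshoot: %carb + %OM exceeds 100 by up to {overshoot:.3g} "
            f"on {int(clipped.sum())} sample(s); silicates clipped to 0",
            ClosureWarning,
            stacklevel=2,
        )
    return CompositionClosure(carb, om, np.where(clipped, 0.0, sil_raw), clipped)


@dataclass
class FluxEnsemble:
    """Per-member TOC and lithogenic fluxes at each retained sample."""

    depths: np.ndarray  # (n_samples,)
    age_ce: np.ndarray  # (members, n_samples), mid-sample age per member
    toc_flux: np.ndarray  # (members, n_samples), g m-2 yr-1
    l_flux: np.ndarray  # (members, n_samples)
    collection_year: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.age_ce.shape == self.toc_flux.shape == self.l_flux.shape):
            raise ParameterError("flux ensemble matrices disagree in shape")
        if np.any(self.toc_flux < 0) or np.any(self.l_flux < 0):
            raise DataError("fluxes must be >= 0")

    @property
    def n_members(self) -> int:
        return self.age_ce.shape[0]

    def series(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(ages_ce, values) matrices for ``which`` in {'toc_flux', 'l_flux'}."""
        try:
            return self.age_ce, getattr(self, which)
        except AttributeError:
            raise ParameterError(f"unknown flux variable {which!r}") from None

    def median_series(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble-median (age, value) per sample, sorted by age."""
        ages, vals = self.series(which)
        t = np.median(ages, axis=0)
        v = np.median(vals, axis=0)
        order = np.argsort(t)
        return t[order], v[order]

    def to_long(self) -> pd.DataFrame:
        m, n = self.age_ce.shape
        return pd.DataFrame(
            {
                "depth": np.tile(self.depths, m),
                "member": np.repeat(np.arange(m), n),
                "age_ce": self.age_ce.ravel(),
                "toc_flux": self.toc_flux.ravel(),
                "l_flux": self.l_flux.ravel(),
            }
        )


def _sample_edges(depths: np.ndarray) -> np.ndarray:
    """Interval edges at midpoints between neighbouring samples."""
    e = np.empty(depths.size + 1)
    e[1:-1] = 0.5 * (depths[:-1] + depths[1:])
    e[0] = depths[0]
    e[-1] = depths[-1]
    return e


def compute_fluxes(
    rec: pd.DataFrame,
    ens: AgeDepthEnsemble,
    *,
    density_fallback: float | None = None,
    om_factor: float = VAN_BEMMELEN_FACTOR,
    exclude_events: bool = True,
) -> FluxEnsemble:
    """TOC and lithogenic fluxes per ensemble member and sample.

    ``rec`` needs columns ``depth, toc, tic`` and ``density`` (g/cm3); missing
    densities fall back to ``density_fallback`` when given.  Samples flagged
    truthy in an optional ``event`` column are dropped when
    ``exclude_events`` is set.
    """
    for col in ("depth", "toc", "tic"):
        if col not in rec.columns:
            raise DataError(f"proxy table missing required column '{col}'")
    rec = rec.sort_values("depth").reset_index(drop=True)
    n_before = len(rec)
    if exclude_events and "event" in rec.columns:
        rec = rec.loc[~rec["event"].fillna(False).astype(bool)].reset_index(drop=True)
    depths = rec["depth"].to_numpy(float)
    if np.any(np.diff(depths) <= 0):
        raise DataError("sample depths must be strictly increasing and unique")
    if len(rec) < 2:
        raise DataError("need >= 2 samples to form sedimentation-rate intervals")

    if "density" in rec.columns:
        rho = rec["density"].to_numpy(float)
    else:
        rho = np.full(len(rec), np.nan)
    missing = ~np.isfinite(rho)
    if missing.any():
        if density_fallback is None:
            raise DataError(
                "missing density without fallback at depths "
                f"{depths[missing].tolist()}"
            )
        rho = np.where(missing, density_fallback, rho)
    if np.any(rho <= 0):
        raise DataError("dry bulk density must be > 0")

    toc = rec["toc"].to_numpy(float)
    tic = rec["tic"].to_numpy(float)
    if np.any(toc < 0) or np.any(tic < 0) or np.any(toc + tic > 100 + 1e-9):
        raise DataError("TOC/TIC outside [0, 100] closure bounds")

    edges = _sample_edges(depths)
    sr = sed_rate_ensemble(ens, edges)  # (members, n_samples)
    ages_bc = ensemble_ages_at(ens, depths)
    age_ce = ens.collection_year - ages_bc

    toc_flux = rho[None, :] * sr * (toc[None, :] / 100.0) * 1e4
    l_flux = rho[None, :] * sr * ((100.0 - toc - tic)[None, :] / 100.0) * 1e4
    return FluxEnsemble(
        depths,
        age_ce,
        toc_flux,
        l_flux,
        ens.collection_year,
        meta={"om_factor": om_factor, "n_excluded": int(n_before - depths.size)},
    )


def trap_flux(
    dry_mass: float, trap_area: float, deployment: float, toc: float, tic: float
) -> tuple[float, float, float]:
    """Sediment-trap fluxes (total, TOC, lithogenic), g m-2 yr-1."""
    if dry_mass <= 0 or trap_area <= 0 or deployment <= 0:
        raise ParameterError("dry_mass, trap_area and deployment must be > 0")
    if toc < 0 or tic < 0 or toc + tic > 100:
        raise ParameterError("TOC/TIC must be >= 0 and sum to <= 100")
    total = dry_mass / (trap_area * deployment)
    return total, total * toc / 100.0, total * (100.0 - toc - tic) / 100.0


def bin_ensemble_series(
    ages: np.ndarray,
    values: np.ndarray,
    bin_width: float,
    t0: float,
    t1: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean of ``values`` per (time bin, member).

    ``ages`` and ``values`` are (members, samples); ``values`` may also be a
    1-D vector shared by all members.  Returns ``(bin_centres, matrix,
    occupancy)`` where ``matrix`` is bins x members with NaN for empty bins.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if not t0 < t1:
        raise ParameterError("need t0 < t1")
    ages = np.atleast_2d(np.asarray(ages, dtype=float))
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = np.broadcast_to(values, ages.shape)
    edges = np.arange(t0, t1 + bin_width * (1 - 1e-12), bin_width)
    if edges[-1] < t1:
        edges = np.append(edges, t1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    n_bins = centres.size
    m = ages.shape[0]
    out = np.full((n_bins, m), np.nan)
    occ = np.zeros((n_bins, m), dtype=int)
    for j in range(m):
        idx = np.digitize(ages[j], edges) - 1
        ok = (idx >= 0) & (idx < n_bins) & np.isfinite(values[j])
        if not ok.any():
            continue
        sums = np.bincount(idx[ok], weights=values[j][ok], minlength=n_bins)
        counts = np.bincount(idx[ok], minlength=n_bins)
        filled = counts > 0
        out[filled, j] = sums[filled] / counts[filled]
        occ[:, j] = counts
    return centres, out, occ


def bin_flux_ensemble(
    fe: FluxEnsemble,
    bin_width: float,
    t0: float,
    t1: float,
    which: str = "toc_flux",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-bin x member mean-flux matrix over [t0, t1] CE."""
    ages, vals = fe.series(which)
    centres, mat, occ = bin_ensemble_series(ages, vals, bin_width, t0, t1)
    if not np.isfinite(mat).any():
        raise DataError(f"no samples fall in the window [{t0}, {t1}] CE")
    return centres, mat, occ


def flux_band_summary(
    fe: FluxEnsemble, bin_width: float, t0: float, t1: float
) -> pd.DataFrame:
    """Median and quantile bands per time bin, both flux variables."""
    rows = {}
    for which in ("toc_flux", "l_flux"):
        centres, mat, _ = bin_flux_ensemble(fe, bin_width, t0, t1, which)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanpercentile(mat, [50, 25, 75, 2.5, 97.5], axis=1)
        rows[which] = q
    return pd.DataFrame(
        {
            "bin_centre": centres,
            **{
                f"{w}_{lab}": rows[w][i]
                for w in rows
                for i, lab in enumerate(["median", "q25", "q75", "q2_5", "q97_5"])
            },
        }
    )


def core_top_flux(fe: FluxEnsemble, max_depth: float = 1.0) -> dict:
    """Mean ensemble-median flux over samples in the topmost ``max_depth`` cm.

    Falls back to the single shallowest sample when nothing lies above
    ``max_depth`` (coarsely sampled cores).
    """
    sel = fe.depths <= max_depth
    if not sel.any():
        sel = fe.depths == fe.depths.min()
    med_toc = np.median(fe.toc_flux[:, sel], axis=0)
    med_l = np.median(fe.l_flux[:, sel], axis=0)
    return {
        "toc_flux": float(med_toc.mean()),
        "l_flux": float(med_l.mean()),
        "n_samples": int(sel.sum()),
    }
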