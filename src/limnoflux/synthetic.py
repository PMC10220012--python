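"""Synthetic sediment cores with known ground truth.

Everything downstream (age model, fluxes, change points, ordination) gets a
parameter-recovery target from this module: a piecewise-linear true
chronology built from gamma-autoregressive section accumulations, dated
horizons drawn around the truth, proxy series with step/ramp regime changes
expressed in time, and Dirichlet-multinomial diatom assemblages whose
planktonic share rises after a configured year.

All randomness flows from explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from limnoflux.calibration import CalibrationCurve
from limnoflux.errors import ParameterError, RangeError, SchemaError

__all__ = [
    "TrueChronology",
    "RegimeSpec",
    "simulate_chronology",
    "chronology_from_rate_profile",
    "simulate_dates",
    "simulate_proxies",
    "simulate_diatoms",
    "make_transect",
    "write_transect",
    "LAKE_DEFAULTS",
]


@dataclass(frozen=True)
class TrueChronology:
    """Piecewise-linear depth -> age mapping with known section accumulations.

    Ages increase downward; internally they are years before collection, the
    reported axis is calendar year CE (``top_age`` is the CE age of the
    sediment surface).
    """

    section_boundaries: np.ndarray  # cm, starting at 0
    section_accumulation: np.ndarray  # yr/cm, > 0
    top_age: float  # calendar year CE at depth 0

    def __post_init__(self) -> None:
        b = np.asarray(self.section_boundaries, dtype=float)
        a = np.asarray(self.section_accumulation, dtype=float)
        if b.size != a.size + 1 or b[0] != 0:
            raise ParameterError("boundaries must start at 0 and bracket each section")
        if np.any(np.diff(b) <= 0):
            raise ParameterError("section boundaries must increase")
        if np.any(a <= 0):
            raise ParameterError("accumulation values must be > 0")
        object.__setattr__(self, "section_boundaries", b)
        object.__setattr__(self, "section_accumulation", a)

    @property
    def depth_span(self) -> float:
        return float(self.section_boundaries[-1])

    def _cum_years(self) -> np.ndarray:
        widths = np.diff(self.section_boundaries)
        return np.concatenate([[0.0], np.cumsum(widths * self.section_accumulation)])

    def age_offset(self, depths) -> np.ndarray:
        """Years of sediment above ``depths`` (age relative to the surface)."""
        d = np.atleast_1d(np.asarray(depths, dtype=float))
        if np.any(d < 0) or np.any(d > self.depth_span + 1e-9):
            raise RangeError(f"depth outside core [0, {self.depth_span}] cm")
        return np.interp(d, self.section_boundaries, self._cum_years())

    def age_ce(self, depths) -> np.ndarray:
        """True calendar age (yr CE) at the given depths."""
        return self.top_age - self.age_offset(depths)

    def depth_at_age_ce(self, ages_ce) -> np.ndarray:
        """Inverse mapping (ages within the modelled span)."""
        offs = self.top_age - np.atleast_1d(np.asarray(ages_ce, dtype=float))
        cum = self._cum_years()
        if np.any(offs < -1e-9) or np.any(offs > cum[-1] + 1e-9):
            raise RangeError("age outside the chronology span")
        return np.interp(offs, cum, self.section_boundaries)


@dataclass(frozen=True)
class RegimeSpec:
    """A step or ramp change in one proxy variable at a calendar year."""

    variable: str
    change_year: float
    pre_level: float
    post_level: float
    change_shape: str = "step"  # 'step' | 'ramp'
    ramp_duration: float = 0.0
    noise_sd: float = 0.0
    autocorrelation: float = 0.0

    def __post_init__(self) -> None:
        if self.change_shape not in {"step", "ramp"}:
            raise ParameterError("change_shape must be 'step' or 'ramp'")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0 <= self.autocorrelation < 1):
            raise ParameterError("autocorrelation must lie in [0, 1)")
        if self.change_shape == "ramp" and self.ramp_duration <= 0:
            raise ParameterError("ramp_duration must be > 0 for ramps")


def simulate_chronology(
    n_sections: int,
    thickness: float,
    acc_mean: float,
    acc_shape: float = 1.5,
    memory: float = 0.7,
    top_age: float = 2015.0,
    seed: int | np.random.SeedSequence | None = None,
) -> TrueChronology:
    """Gamma-autoregressive section accumulations (the age model's generative form)."""
    if n_sections < 1 or thickness <= 0 or acc_mean <= 0 or acc_shape <= 0:
        raise ParameterError("n_sections, thickness, acc_mean, acc_shape must be positive")
    if not (0 <= memory <= 1):
        raise ParameterError("memory must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    scale = acc_mean / acc_shape
    a = np.empty(n_sections)
    a[0] = rng.gamma(acc_shape, scale)
    for i in range(1, n_sections):
        g = rng.gamma(acc_shape, scale)
        a[i] = memory * a[i - 1] + (1 - memory) * g
    bounds = np.arange(n_sections + 1) * thickness
    return TrueChronology(bounds, a, top_age)


def chronology_from_rate_profile(
    rate_of_age,
    n_sections: int,
    thickness: float,
    rel_sd: float = 0.0,
    top_age: float = 2015.0,
    seed: int | np.random.SeedSequence | None = None,
) -> TrueChronology:
    """Chronology whose accumulation follows a time-dependent profile.

    ``rate_of_age(age_ce) -> yr/cm`` is evaluated at the age of each section
    top going downward, optionally jittered with relative lognormal noise, so
    accumulation-rate regime shifts can be placed at known calendar years.
    """
    rng = np.random.default_rng(seed)
    a = np.empty(n_sections)
    age = float(top_age)
    for i in range(n_sections):
        base = float(rate_of_age(age))
        if base <= 0:
            raise ParameterError("rate profile must be > 0 everywhere")
        if rel_sd > 0:
            base *= float(np.exp(rng.normal(0.0, rel_sd) - rel_sd**2 / 2))
        a[i] = base
        age -= base * thickness
    bounds = np.arange(n_sections + 1) * thickness
    return TrueChronology(bounds, a, top_age)


def simulate_dates(
    chron: TrueChronology,
    depths,
    errors,
    types,
    curve: CalibrationCurve | None = None,
    seed: int | np.random.SeedSequence | None = None,
    collection_year: float = 2015.0,
) -> pd.DataFrame:
    """Observed dated horizons around the true chronology.

    Calendar-type dates are N(true age CE, error^2); radiocarbon dates map
    the true calendar age through the curve and add N(0, error^2) in 14C yr.
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    types = list(types)
    if not (depths.size == errors.size == len(types)):
        raise ParameterError("depths, errors and types must have equal length")
    if np.any(errors <= 0):
        raise ParameterError("date errors must be > 0")
    if np.any(depths < 0) or np.any(depths > chron.depth_span):
        raise RangeError("date depth outside the core")
    rng = np.random.default_rng(seed)
    true_ce = chron.age_ce(depths)

    ages = np.empty(depths.size)
    for i, typ in enumerate(types):
        if typ == "radiocarbon":
            if curve is None:
                raise ParameterError("radiocarbon dates need a calibration curve")
            cal_bp = 1950.0 - true_ce[i]
            lo, hi = curve.span
            if not (lo <= cal_bp <= hi):
                raise RangeError(
                    f"true age {cal_bp:.0f} cal BP outside curve span [{lo}, {hi}]"
                )
            ages[i] = curve.c14_at(cal_bp) + rng.normal(0.0, errors[i])
        else:
            ages[i] = true_ce[i] + rng.normal(0.0, errors[i])
    return pd.DataFrame(
        {
            "labID": [f"sim_{i}" for i in range(depths.size)],
            "age": ages,
            "error": errors,
            "depth": depths,
            "type": types,
            "excluded": False,
        }
    )


def _regime_mean_curve(regimes: list[RegimeSpec], ages_ce: np.ndarray) -> np.ndarray:
    """Mean level through a chronologically ordered sequence of regime changes."""
    regs = sorted(regimes, key=lambda r: r.change_year)
    level = np.full(ages_ce.shape, regs[0].pre_level, dtype=float)
    for r in regs:
        if r.change_shape == "step":
            level = np.where(ages_ce >= r.change_year, r.post_level, level)
        else:
            t_end = r.change_year + r.ramp_duration
            frac = np.clip((ages_ce - r.change_year) / r.ramp_duration, 0.0, 1.0)
            base = np.where(ages_ce >= r.change_year, r.pre_level, level)
            level = np.where(
                ages_ce >= r.change_year, base + frac * (r.post_level - r.pre_level), level
            )
            level = np.where(ages_ce >= t_end, r.post_level, level)
    return level


def _ar1_noise(n: int, sd: float, phi: float, rng) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return x

#: physical bounds applied after adding noise
_BOUNDS = {
    "toc": (0.0, 100.0),
    "tic": (0.0, 100.0),
    "sand": (0.0, 100.0),
    "silt": (0.0, 100.0),
    "clay": (0.0, 100.0),
    "biosi": (0.0, 100.0),
    "chlorophyll": (0.0, None),
    "density": (1e-3, None),
}


def simulate_proxies(
    chron: TrueChronology,
    regimes: dict[str, list[RegimeSpec]],
    sample_spacing: float,
    seed: int | np.random.SeedSequence | None = None,
    density_mean: float = 0.3,
    density_sd: float = 0.02,
    known_variables: set[str] | None = None,
) -> pd.DataFrame:
    """Depth-resolved proxy table: regime mean curves + AR(1) noise.

    Each variable's mean curve is evaluated at the sample's true age.  TOC
    and TIC are clipped so the lithogenic fraction stays within [0, 100];
    dry bulk density is a positive AR(1) series around ``density_mean``
    unless a 'density' regime is supplied.
    """
    if sample_spacing <= 0:
        raise ParameterError("sample_spacing must be > 0")
    if not isinstance(regimes, dict):  # flat RegimeSpec list: group by variable
        grouped: dict[str, list[RegimeSpec]] = {}
        for r in regimes:
            grouped.setdefault(r.variable, []).append(r)
        regimes = grouped
    if known_variables is not None:
        unknown = set(regimes) - set(known_variables)
        if unknown:
            raise SchemaError(f"regimes reference unknown variables: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    depths = np.arange(sample_spacing / 2, chron.depth_span, sample_spacing)
    ages = chron.age_ce(depths)
    out = pd.DataFrame({"depth": depths, "age_true_ce": ages})

    for var, regs in regimes.items():
        if not regs:
            raise SchemaError(f"empty regime list for variable {var!r}")
        mean = _regime_mean_curve(regs, ages)
        r0 = regs[0]
        series = mean + _ar1_noise(depths.size, r0.noise_sd, r0.autocorrelation, rng)
        lo, hi = _BOUNDS.get(var, (None, None))
        if lo is not None or hi is not None:
            series = np.clip(series, lo if lo is not None else -np.inf,
                             hi if hi is not None else np.inf)
        out[var] = series

    if "density" not in out.columns:
        dens = density_mean + _ar1_noise(depths.size, density_sd, 0.5, rng)
        out["density"] = np.clip(dens, 1e-3, None)

    # keep the closure valid: lithogenic fraction within [0, 100]
    if {"toc", "tic"} <= set(out.columns):
        total = out["toc"] + out["tic"]
        over = total > 100
        if over.any():
            scale = 100.0 / total[over]
            out.loc[over, "toc"] *= scale
            out.loc[over, "tic"] *= scale
    return out


def simulate_diatoms(
    chron: TrueChronology,
    n_taxa: int,
    planktonic_taxa,
    change_year: float,
    concentration: float = 50.0,
    valves_per_sample: int = 400,
    spike: int = 100_000,
    sample_spacing: float = 4.0,
    planktonic_share: tuple[float, float] = (0.15, 0.6),
    cd_ratio: float = 0.08,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Dirichlet-multinomial valve counts with a post-``change_year``
    planktonic rise, plus chrysophyte-cyst and microsphere columns."""
    if n_taxa < 2:
        raise ParameterError("need >= 2 taxa")
    if valves_per_sample < 1:
        raise ParameterError("valves_per_sample must be >= 1")
    if concentration <= 0:
        raise ParameterError("concentration must be > 0")
    planktonic_taxa = sorted(set(int(i) for i in planktonic_taxa))
    if planktonic_taxa and (min(planktonic_taxa) < 0 or max(planktonic_taxa) >= n_taxa):
        raise ParameterError("planktonic taxon index out of range")
    rng = np.random.default_rng(seed)

    depths = np.arange(sample_spacing / 2, chron.depth_span, sample_spacing)
    ages = chron.age_ce(depths)
    plank = np.zeros(n_taxa, dtype=bool)
    plank[planktonic_taxa] = True
    n_plank = int(plank.sum())
    n_benth = n_taxa - n_plank

    counts = np.zeros((depths.size, n_taxa), dtype=int)
    pre, post = planktonic_share
    for i, age in enumerate(ages):
        share = post if age >= change_year else pre
        target = np.empty(n_taxa)
        if n_plank:
            target[plank] = share / n_plank
        target[~plank] = (1 - (share if n_plank else 0.0)) / max(n_benth, 1)
        comp = rng.dirichlet(concentration * target)
        counts[i] = rng.multinomial(valves_per_sample, comp)

    names = [
        (f"plank_{j}" if plank[j] else f"benth_{j}") for j in range(n_taxa)
    ]
    df = pd.DataFrame(counts, columns=names)
    df.insert(0, "depth", depths)
    df["cysts"] = rng.poisson(cd_ratio * valves_per_sample, size=depths.size)
    df["microspheres"] = rng.poisson(100.0, size=depths.size) + 1
    df["spike"] = spike
    df["mass_g"] = np.round(rng.uniform(0.05, 0.15, size=depths.size), 4)
    return df


# ---------------------------------------------------------------------------
# the six-lake transect fixture
#
# Per-lake magnitudes loosely follow the published transect: flux steps after
# 1850/1950 CE, a large 1970s organic-flux step in the ski-area lake, a 1940s
# step in the dammed lake, d13C declines of 1-6 permil and decreasing C/N.

LAKE_DEFAULTS: dict[str, dict] = {
    # silicate watersheds; organic regimes of the undisturbed lakes are
    # anchored at 1850/1950, their lithogenic (accumulation) histories are
    # deliberately heterogeneous in timing and sign
    "CR": dict(acc=(16.0, 13.0, 9.0), acc_years=(1850, 1950), density=0.35,
               toc=(1.0, 1.3, 2.4), toc_years=(1850, 1950),
               d13c=(-25.5, -26.5), d13c_year=1950, cn=(11.0, 9.5), cn_year=1950,
               tic=0.05, sand=8.0, noise_mult=1.0, has_diatoms=True,
               disturbed=False),
    "UR": dict(acc=(16.0, 5.0, 7.0), acc_years=(1935, 1955), density=0.35,
               toc=(2.0, 4.5, 3.5), toc_years=(1935, 1970),
               d13c=(-21.0, -27.0), d13c_year=1935, cn=(13.0, 10.0), cn_year=1935,
               tic=0.05, sand=10.0, noise_mult=2.5, has_diatoms=False,
               disturbed=True,
               overrides={
                   # slow early isotope decline, hump-shaped C/N
                   "d13c": [(1700.0, -21.0, -27.0, "ramp", 250.0)],
                   "cn": [(1800.0, 11.0, 14.0, "ramp", 100.0),
                          (1950.0, 14.0, 10.0, "ramp", 40.0)],
               }),
    "SI": dict(acc=(12.0, 18.0, 9.0), acc_years=(1850, 1950), density=0.30,
               toc=(2.0, 1.6, 3.5), toc_years=(1850, 1950),
               d13c=(-26.0, -32.0), d13c_year=1950, cn=(12.0, 9.0), cn_year=1950,
               tic=0.05, sand=6.0, noise_mult=1.0, has_diatoms=False,
               disturbed=False),
    "AC": dict(acc=(15.0, 11.0, 12.0), acc_years=(1800, 1885), density=0.28,
               toc=(4.0, 5.5, 9.0), toc_years=(1850, 1950),
               d13c=(-27.0, -29.0), d13c_year=1950, cn=(12.0, 10.0), cn_year=1950,
               tic=0.3, sand=6.0, noise_mult=1.0, has_diatoms=True,
               disturbed=False),
    # carbonate watersheds
    # SA's organic-flux step reproduces the published magnitude:
    # 0.45 g/cm3 * (1/7) cm/yr * 2.2% * 1e4/100 = 14 g m-2 yr-1 before 1970,
    # 0.45 * (1/3) * 4.4% * 100 = 66 g m-2 yr-1 after
    "SA": dict(acc=(12.0, 7.0, 3.0), acc_years=(1940, 1970), density=0.45,
               toc=(2.2, 2.2, 4.4), toc_years=(1940, 1970),
               d13c=(-18.0, -24.0), d13c_year=1980, cn=(14.0, 18.0), cn_year=1980,
               tic=6.0, sand=12.0, noise_mult=2.5, has_diatoms=True,
               disturbed=True,
               overrides={
                   # isotope rise through the IR, abrupt GA decline; rising C/N
                   "d13c": [(1850.0, -18.0, -12.0, "ramp", 80.0),
                            (1980.0, -12.0, -24.0, "step", 0.0)],
                   "cn": [(1850.0, 14.0, 18.0, "ramp", 60.0)],
               }),
    "MA": dict(acc=(10.0, 15.0, 8.0), acc_years=(1850, 1930), density=0.40,
               toc=(0.8, 0.9, 1.4), toc_years=(1850, 1950),
               d13c=(-23.0, -24.0), d13c_year=1950, cn=(9.0, 8.8), cn_year=1950,
               tic=4.0, sand=10.0, noise_mult=1.0, has_diatoms=False,
               disturbed=False),
}

#: pseudo-ICP element columns emitted by the transect generator
DETRITAL_ELEMENTS = ["al", "fe", "k", "ti"]
ELEMENT_COLUMNS = DETRITAL_ELEMENTS + ["ca", "sr", "p", "mn"]


def _transect_lake(name: str, spec: dict, seed_seq, collection_year: float):
    """Simulate one lake of the transect; returns (dates, proxies, diatoms, truth)."""
    s_chron, s_dates, s_prox, s_diat = seed_seq.spawn(4)
    n_sections = 20
    thickness = 4.0

    acc_pre, acc_mid, acc_post = spec["acc"]
    acc_y1, acc_y2 = spec["acc_years"]

    def rate(age_ce: float) -> float:
        if age_ce >= acc_y2:
            return acc_post
        if age_ce >= acc_y1:
            return acc_mid
        return acc_pre

    chron = chronology_from_rate_profile(
        rate, n_sections, thickness, rel_sd=0.05, top_age=collection_year, seed=s_chron
    )

    # dated horizons: dense calendar (210Pb/137Cs-like) dates in the upper
    # core, sparser calendar/14C control below
    top_depths = np.arange(2.0, 32.0, 4.0)
    top_errors = np.linspace(2.0, 10.0, top_depths.size)
    deep_depths = np.arange(40.0, chron.depth_span - 1.0, 15.0)
    deep_errors = np.full(deep_depths.size, 25.0)
    depths = np.concatenate([top_depths, deep_depths])
    errors = np.concatenate([top_errors, deep_errors])
    types = ["pb210"] * top_depths.size + ["calendar"] * deep_depths.size
    dates = simulate_dates(
        chron, depths, errors, types, seed=s_dates, collection_year=collection_year
    )

    toc_pre, toc_mid, toc_post = spec["toc"]
    y1, y2 = spec["toc_years"]
    nm = spec["noise_mult"]
    regimes = {
        "toc": [
            RegimeSpec("toc", y1, toc_pre, toc_mid, noise_sd=0.08 * max(toc_pre, 0.5),
                       autocorrelation=0.3),
            RegimeSpec("toc", y2, toc_mid, toc_post),
        ],
        "tic": [RegimeSpec("tic", 1850, spec["tic"], spec["tic"],
                           noise_sd=0.05 * max(spec["tic"], 0.02), autocorrelation=0.2)],
        "d13c": [RegimeSpec("d13c", spec["d13c_year"], spec["d13c"][0], spec["d13c"][1],
                            change_shape="ramp", ramp_duration=25.0,
                            noise_sd=0.25 * nm, autocorrelation=0.3)],
        "cn": [RegimeSpec("cn", spec["cn_year"], spec["cn"][0], spec["cn"][1],
                          change_shape="ramp", ramp_duration=25.0,
                          noise_sd=0.35 * nm, autocorrelation=0.3)],
        "sand": [RegimeSpec("sand", acc_y1, spec["sand"], spec["sand"] * 0.7,
                            noise_sd=1.0, autocorrelation=0.2)],
    }
    for var, regs in spec.get("overrides", {}).items():
        noise = {"d13c": 0.25 * nm, "cn": 0.35 * nm}.get(var, 0.25 * nm)
        regimes[var] = [
            RegimeSpec(var, year, pre, post, change_shape=shape,
                       ramp_duration=dur, noise_sd=noise, autocorrelation=0.3)
            for year, pre, post, shape, dur in regs
        ]
    # pseudo-ICP elements: the detrital group (al/fe/k/ti) tracks the lake's
    # accumulation history, the rest follow carbonate, productivity or redox
    # behaviour so the compositional matrix is not a single factor
    rng_el = np.random.default_rng(s_prox.spawn(1)[0])
    for j, el in enumerate(DETRITAL_ELEMENTS):
        base = 1000.0 * (j + 1)
        lvl_mid = base * acc_pre / acc_mid
        lvl_post = base * acc_pre / acc_post * rng_el.uniform(0.95, 1.05)
        regimes[el] = [
            RegimeSpec(el, acc_y1, base, lvl_mid, noise_sd=0.08 * base,
                       autocorrelation=0.2),
            RegimeSpec(el, acc_y2, lvl_mid, lvl_post),
        ]
    # carbonate-hosted elements scale with TIC level
    for el, mult in (("ca", 40.0), ("sr", 0.8)):
        lvl = 1000.0 + mult * 100.0 * spec["tic"]
        regimes[el] = [RegimeSpec(el, 1850, lvl, lvl, noise_sd=0.1 * lvl,
                                  autocorrelation=0.4)]
    # productivity-linked phosphorus follows the organic-matter steps
    regimes["p"] = [
        RegimeSpec("p", y1, 300.0 * toc_pre, 300.0 * toc_mid, noise_sd=40.0,
                   autocorrelation=0.3),
        RegimeSpec("p", y2, 300.0 * toc_mid, 300.0 * toc_post),
    ]
    # redox-sensitive manganese: autocorrelated noise, no regime signal
    regimes["mn"] = [RegimeSpec("mn", 1850, 500.0, 500.0, noise_sd=120.0,
                                autocorrelation=0.7)]
    proxies = simulate_proxies(
        chron, regimes, sample_spacing=1.0, seed=s_prox,
        density_mean=spec["density"], density_sd=0.015,
    )
    # grain-size closure companions for the sand column
    rng_gs = np.random.default_rng(s_prox.spawn(2)[1])
    silt = np.clip(60.0 + rng_gs.normal(0, 2.0, len(proxies)), 0, 95)
    proxies["silt"] = np.minimum(silt, 100.0 - proxies["sand"])
    proxies["clay"] = 100.0 - proxies["sand"] - proxies["silt"]

    diatoms = None
    if spec["has_diatoms"]:
        diatoms = simulate_diatoms(
            chron, n_taxa=12, planktonic_taxa=[0, 1, 2], change_year=1950.0,
            seed=s_diat,
        )

    truth = {
        "top_age": chron.top_age,
        "section_boundaries": chron.section_boundaries.tolist(),
        "section_accumulation": chron.section_accumulation.tolist(),
        "true_ages_ce": chron.age_ce(proxies["depth"].to_numpy()).tolist(),
        "regimes": {
            var: [asdict(r) for r in regs] for var, regs in regimes.items()
        },
        "cp_years": [1850.0, 1950.0],
        "toc_change_years": list(spec["toc_years"]),
        "disturbed": spec["disturbed"],
    }
    return dates, proxies, diatoms, truth


def make_transect(
    seed: int | np.random.SeedSequence = 0,
    collection_year: float = 2015.0,
    lakes: list[str] | None = None,
) -> dict[str, dict]:
    """Six-lake synthetic transect with regime steps at 1850 and 1950 CE.

    Returns ``{lake: {'dates', 'proxies', 'diatoms', 'truth'}}``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = lakes if lakes is not None else list(LAKE_DEFAULTS)
    unknown = set(names) - set(LAKE_DEFAULTS)
    if unknown:
        raise ParameterError(f"unknown lakes: {sorted(unknown)}")
    children = ss.spawn(len(names))
    out = {}
    for name, child in zip(names, children):
        dates, proxies, diatoms, truth = _transect_lake(
            name, LAKE_DEFAULTS[name], child, collection_year
        )
        out[name] = {
            "dates": dates,
            "proxies": proxies,
            "diatoms": diatoms,
            "truth": truth,
        }
    return out


def write_transect(transect: dict[str, dict], out_dir) -> Path:
    """Write the fixture as delimited tables plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = {}
    for lake, bundle in transect.items():
        bundle["dates"].to_csv(out / f"{lake}_dates.csv", index=False)
        bundle["proxies"].to_csv(out / f"{lake}_proxies.csv", index=False)
        if bundle["diatoms"] is not None:
            bundle["diatoms"].to_csv(out / f"{lake}_diatoms.csv", index=False)
        truths[lake] = bundle["truth"]
    with open(out / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)
    return out
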