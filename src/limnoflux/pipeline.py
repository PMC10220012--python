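"""End-to-end orchestration: chronology -> fluxes -> change points -> PCA.

Stages are deterministic given (config, seed): one seed sequence is spawned
per (lake, stage) in a fixed order.  A failure in one lake is quarantined
and recorded; the run only fails when every lake fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from limnoflux import io as lio
from limnoflux.agemodel import AgeDepthEnsemble, ensemble_ages_at, fit_age_model
from limnoflux.calibration import CalibrationCurve
from limnoflux.changepoint import (
    cumsum_changepoints,
    cumsum_curve,
    derivative_changepoints,
    fit_gam_trend,
)
from limnoflux.config import PipelineConfig
from limnoflux.errors import LimnofluxError
from limnoflux.flux import FluxEnsemble, compute_fluxes, flux_band_summary
from limnoflux.ordination import (
    AgeUncertainSeries,
    age_uncertain_pca,
    hellinger_pca,
    standardized_pca,
)

__all__ = ["LakeResult", "PipelineResult", "run_pipeline", "run_lake", "build_series"]

logger = logging.getLogger(__name__)


@dataclass
class LakeResult:
    name: str
    ensemble: AgeDepthEnsemble
    fluxes: FluxEnsemble
    proxies: pd.DataFrame
    changepoints: pd.DataFrame
    comp_pca: "object"
    diatom_pca: "object | None" = None
    timings: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    lakes: dict[str, LakeResult]
    failures: dict[str, str]
    organic_pca: "object | None"
    lithogenic_pca: "object | None"
    summary: dict


def _median_proxy_series(proxies: pd.DataFrame, ens: AgeDepthEnsemble, column: str):
    sub = proxies.dropna(subset=[column])
    depths = sub["depth"].to_numpy(float)
    ages_ce = ens.collection_year - np.median(ensemble_ages_at(ens, depths), axis=0)
    vals = sub[column].to_numpy(float)
    order = np.argsort(ages_ce)
    return ages_ce[order], vals[order]


def _changepoint_report(
    name: str, series: dict[str, tuple[np.ndarray, np.ndarray]], settings, rng
) -> pd.DataFrame:
    rows = []
    for var, (t, v) in series.items():
        try:
            cs = cumsum_changepoints(
                cumsum_curve(v), t, settings.min_segment, settings.slope_delta_min
            )
            for d in cs.detail:
                rows.append(
                    dict(lake=name, variable=var, method="cumsum",
                         cp_time=d["cp_time"], sign=d["sign_change"],
                         statistic=d["statistic"], interval_start=np.nan,
                         interval_end=np.nan)
                )
        except LimnofluxError as exc:
            logger.warning("%s %s cumsum skipped: %s", name, var, exc)
        try:
            fit = fit_gam_trend(t, v, basis_dim=settings.basis_dim,
                                method=settings.smoothing)
            gm = derivative_changepoints(
                fit, n_draws=settings.n_draws, level=settings.level,
                seed=rng.integers(2**32),
            )
            for d in gm.detail:
                rows.append(
                    dict(lake=name, variable=var, method="gam",
                         cp_time=0.5 * (d["t_start"] + d["t_end"]),
                         sign=d["sign"], statistic=d["statistic"],
                         interval_start=d["t_start"], interval_end=d["t_end"])
                )
        except LimnofluxError as exc:
            logger.warning("%s %s gam skipped: %s", name, var, exc)
    cols = ["lake", "variable", "method", "cp_time", "sign", "statistic",
            "interval_start", "interval_end"]
    return pd.DataFrame(rows, columns=cols)


def run_lake(
    lake_cfg,
    config: PipelineConfig,
    curve: CalibrationCurve,
    seed_seq: np.random.SeedSequence,
    base: Path,
) -> LakeResult:
    """All per-lake stages; raises on failure (quarantined by the caller)."""
    timings = {}
    s_age, s_cp = seed_seq.spawn(2)

    t_start = time.perf_counter()
    dates, _ = lio.read_date_table(base / lake_cfg.dates)
    proxies, proxy_report = lio.read_proxy_table(
        base / lake_cfg.proxies,
        require_density=config.flux.density_fallback is None,
    )
    for flag in proxy_report.flags:
        logger.warning("%s proxies: %s", lake_cfg.name, flag)

    settings = dataclasses.replace(
        config.agemodel,
        collection_year=config.collection_year,
        acc_mean=lake_cfg.acc_mean or config.agemodel.acc_mean,
    )
    core_depth = lake_cfg.core_depth or float(
        max(dates["depth"].max(), proxies["depth"].max())
    )
    ens = fit_age_model(dates, curve, core_depth=core_depth, settings=settings,
                        seed=s_age)
    timings["agemodel_s"] = time.perf_counter() - t_start

    t0 = time.perf_counter()
    fluxes = compute_fluxes(
        proxies, ens,
        density_fallback=config.flux.density_fallback,
        om_factor=config.flux.om_factor,
        exclude_events=config.flux.exclude_events,
    )
    timings["flux_s"] = time.perf_counter() - t0

    # change points on the ensemble-median series
    t0 = time.perf_counter()
    series = {}
    for var in config.changepoint.variables:
        if var in ("toc_flux", "l_flux"):
            series[var] = fluxes.median_series(var)
        elif var in proxies.columns:
            series[var] = _median_proxy_series(proxies, ens, var)
    rng_cp = np.random.default_rng(s_cp)
    cps = _changepoint_report(lake_cfg.name, series, config.changepoint, rng_cp)
    timings["changepoint_s"] = time.perf_counter() - t0

    # per-lake compositional PCA (TOC, TIC, elements, % sand)
    t0 = time.perf_counter()
    comp_cols = [c for c in proxies.columns
                 if c in ("toc", "tic", "sand") or c in _element_columns(proxies)]
    comp_frame = proxies[["depth", *comp_cols]].dropna()
    comp = standardized_pca(comp_frame[comp_cols], standardize=True)
    comp.meta["depths"] = comp_frame["depth"].to_numpy(float)
    timings["comp_pca_s"] = time.perf_counter() - t0

    diatom_pca = None
    if lake_cfg.diatoms:
        counts, _ = lio.read_diatom_table(base / lake_cfg.diatoms)
        try:
            diatom_pca = hellinger_pca(counts)
        except LimnofluxError as exc:
            logger.warning("%s diatom PCA skipped: %s", lake_cfg.name, exc)

    return LakeResult(lake_cfg.name, ens, fluxes, proxies, cps, comp, diatom_pca,
                      timings)


def _element_columns(proxies: pd.DataFrame) -> list[str]:
    known = {"al", "as", "ca", "cd", "co", "cr", "cu", "fe", "k", "li", "mg",
             "mn", "mo", "na", "ni", "p", "pb", "s", "se", "si", "sr", "ti",
             "v", "zn"}
    return [c for c in proxies.columns if c.lower() in known]


def build_series(
    lakes: dict[str, LakeResult],
    variables,
    n_members: int,
) -> list[AgeUncertainSeries]:
    """Assemble age-uncertain series (one per lake x variable) for the PCA."""
    out = []
    for name, lr in lakes.items():
        ens, fluxes, proxies = lr.ensemble, lr.fluxes, lr.proxies
        M = min(n_members, fluxes.n_members)
        for var in variables:
            if var in ("toc_flux", "l_flux"):
                ages, vals = fluxes.series(var)
                out.append(AgeUncertainSeries(f"{name}:{var}", ages[:M], vals[:M]))
            elif var == "pc1_comp":
                comp_scores = lr.comp_pca.scores[:, 0]
                depths = lr.comp_pca.meta["depths"]
                ages = ens.collection_year - ensemble_ages_at(ens, depths)
                out.append(AgeUncertainSeries(f"{name}:pc1_comp", ages[:M], comp_scores))
            elif var in proxies.columns:
                sub = proxies.dropna(subset=[var])
                depths = sub["depth"].to_numpy(float)
                ages = ens.collection_year - ensemble_ages_at(ens, depths)
                out.append(
                    AgeUncertainSeries(f"{name}:{var}", ages[:M], sub[var].to_numpy(float))
                )
            else:
                logger.warning("%s: variable %s not available; skipped", name, var)
    return out


def run_pipeline(config: PipelineConfig, base: Path | None = None) -> PipelineResult:
    base = Path(base) if base is not None else Path(".")
    config.validate_files(base)
    out_dir = base / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = lio.config_hash(config.as_dict())
    seed = config.seed
    root = np.random.SeedSequence(seed)
    # fixed spawn order: one child per configured lake, then one per PCA set
    children = root.spawn(len(config.lakes) + 2)

    curve = (
        lio.read_calibration_curve(base / config.calibration_curve)
        if config.calibration_curve
        else CalibrationCurve.identity()
    )

    lakes: dict[str, LakeResult] = {}
    failures: dict[str, str] = {}
    for lake_cfg, child in zip(config.lakes, children):
        try:
            lr = run_lake(lake_cfg, config, curve, child, base)
            lakes[lake_cfg.name] = lr
        except Exception as exc:  # per-lake quarantine
            logger.error("lake %s failed: %s", lake_cfg.name, exc)
            failures[lake_cfg.name] = f"{type(exc).__name__}: {exc}"

    if not lakes:
        raise LimnofluxError(f"all lakes failed: {failures}")

    def stamp(df, path, stage):
        lio.write_table(df, path, config_hash=chash, seed=seed, stage=stage)

    for name, lr in lakes.items():
        stamp(lr.ensemble.summary(), out_dir / f"{name}_chronology.csv", "agemodel")
        stamp(lr.fluxes.to_long(), out_dir / f"{name}_flux_long.csv", "flux")
        stamp(
            flux_band_summary(lr.fluxes, config.pca.bin_width, config.pca.t0,
                              config.pca.t1),
            out_dir / f"{name}_flux_summary.csv", "flux",
        )
        stamp(lr.changepoints, out_dir / f"{name}_changepoints.csv", "changepoint")
        comp_df = pd.DataFrame(
            lr.comp_pca.loadings,
            columns=[f"pc{k+1}" for k in range(lr.comp_pca.loadings.shape[1])],
        )
        comp_df.insert(0, "variable", lr.comp_pca.variables)
        stamp(comp_df, out_dir / f"{name}_comp_pca_loadings.csv", "pca")

    organic_pca = lithogenic_pca = None
    pca_cfg = config.pca
    if len(lakes) >= 1:
        try:
            org_series = build_series(lakes, pca_cfg.organic, pca_cfg.n_members_used)
            organic_pca = age_uncertain_pca(
                org_series, pca_cfg.bin_width, pca_cfg.t0, pca_cfg.t1,
                n_members_used=pca_cfg.n_members_used,
                n_components=pca_cfg.n_components, seed=children[-2],
            )
            stamp(organic_pca.band_table(0), out_dir / "pc_au_organic.csv", "pca")
        except LimnofluxError as exc:
            logger.warning("organic age-uncertain PCA skipped: %s", exc)
        try:
            lit_series = build_series(lakes, pca_cfg.lithogenic, pca_cfg.n_members_used)
            lithogenic_pca = age_uncertain_pca(
                lit_series, pca_cfg.bin_width, pca_cfg.t0, pca_cfg.t1,
                n_members_used=pca_cfg.n_members_used,
                n_components=pca_cfg.n_components, seed=children[-1],
            )
            stamp(lithogenic_pca.band_table(0), out_dir / "pc_au_lithogenic.csv", "pca")
        except LimnofluxError as exc:
            logger.warning("lithogenic age-uncertain PCA skipped: %s", exc)

    summary = {
        "config_hash": chash,
        "seed": seed,
        "lakes_ok": sorted(lakes),
        "lakes_failed": failures,
        "timings": {n: lr.timings for n, lr in lakes.items()},
        "organic_pc1_variance": (
            float(np.nanmedian(organic_pca.variance_fractions[:, 0]))
            if organic_pca is not None else None
        ),
        "lithogenic_pc1_variance": (
            float(np.nanmedian(lithogenic_pca.variance_fractions[:, 0]))
            if lithogenic_pca is not None else None
        ),
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=1))
    return PipelineResult(lakes, failures, organic_pca, lithogenic_pca, summary)
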