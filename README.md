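# limnoflux

Reconstruction of organic-carbon (TOC) and lithogenic fluxes from lake-sediment
cores under age-model uncertainty, with the downstream statistics used in
multi-lake regional syntheses:

- **Bayesian age-depth modelling** (`limnoflux.agemodel`): gamma-autoregressive
  accumulation prior, Student-t date likelihood (radiocarbon dates evaluated in
  14C space through a calibration curve), Metropolis-within-Gibbs sampling with
  adaptive proposals, monotone posterior ensembles.
- **Flux engine** (`limnoflux.flux`): carbonate/organic-matter/silicate
  compositional closure (`%carb = 100.09·TIC/12.01`, `%OM = 1.724·TOC`), and
  per-ensemble-member `TOC_flux = ρ·SR·%TOC/100·10⁴` and
  `L_flux = ρ·SR·(100−%TOC−%TIC)/100·10⁴` in g·m⁻²·yr⁻¹; sediment-trap fluxes;
  time binning with quantile band summaries.
- **Change points** (`limnoflux.changepoint`): CumSum of deviations from the
  mean with slope-sign-change detection, and penalized-spline (GAM) trends
  whose first-derivative *simultaneous* confidence band marks periods of
  significant change.
- **Ordination** (`limnoflux.ordination`): standardized (compositional) PCA,
  Hellinger-transformed diatom PCA with the 1%-abundance/2-occurrence filter,
  probabilistic PCA (EM, missing data integrated out), and age-uncertain PCA
  that bins every series per chronology-ensemble member and summarizes scores
  with highest-density bands. Diatom summaries (relative abundances,
  chrysophyte/diatom ratio, microsphere-spike valve concentrations).
- **Synthetic cores** (`limnoflux.synthetic`): chronologies, dated horizons,
  proxy regimes (steps/ramps + AR(1) noise) and Dirichlet-multinomial diatom
  counts with known ground truth, including a six-lake transect fixture with
  regime changes at 1850/1950 CE.
- **IO + pipeline + CLI** (`limnoflux.io`, `limnoflux.pipeline`,
  `limnoflux.cli`): CSV readers/writers with validation reports and provenance
  headers, a YAML-configured end-to-end pipeline with per-lake error
  quarantine, and composable CLI subcommands.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end statistical acceptance
criteria (age-model recovery on 50 cores, CumSum/GAM calibration and power,
ordination oracles, full-transect change-point localization); the other files
are fast unit and property tests.

## CLI

```sh
limnoflux simulate --seed 1 --out fixtures/            # write the synthetic transect
limnoflux agemodel --dates fixtures/CR_dates.csv --out out/CR --seed 1 \
    --n-iter 8000 --burn-in 2000 --n-members 500
limnoflux fluxes --proxies fixtures/CR_proxies.csv \
    --ensemble out/CR.ensemble.csv --out out/CR_flux
limnoflux changepoints --series series.csv --out out/cp.csv --seed 1
limnoflux pca --diatoms fixtures/CR_diatoms.csv --out out/diatom_pca
limnoflux pipeline --config config.yaml
```

A pipeline config lists per-lake input files plus age-model / flux /
change-point / PCA settings; see `limnoflux.config.PipelineConfig` for all
keys and defaults.

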