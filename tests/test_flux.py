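import numpy as np
import pandas as pd
import pytest

from limnoflux.agemodel import AgeDepthEnsemble
from limnoflux.errors import DataError, ParameterError
from limnoflux.flux import (
    CARBONATE_FACTOR,
    ClosureWarning,
    bin_ensemble_series,
    bin_flux_ensemble,
    composition_closure,
    compute_fluxes,
    trap_flux,
)


class TestClosure:
    def test_zero_inputs(self):
        cc = composition_closure(0.0, 0.0)
        assert (cc.carbonates[0], cc.organic_matter[0], cc.silicates[0]) == (0, 0, 100)

    def test_hand_arithmetic(self):
        # 100.09 * 1.2 / 12.01 = 10.0008...
        cc = composition_closure(0.0, 1.2)
        assert cc.carbonates[0] == pytest.approx(100.09 * 1.2 / 12.01, rel=1e-12)

    def test_overshoot_warns(self):
        # TIC = 12.01 -> %carb = 100.09 alone
        with pytest.warns(ClosureWarning):
            cc = composition_closure(0.0, 12.01)
        assert cc.carbonates[0] == pytest.approx(100.09)
        assert cc.silicates[0] == 0.0
        assert cc.clipped[0]

    def test_conservation_without_clipping(self):
        rng = np.random.default_rng(0)
        toc = rng.uniform(0, 10, 500)
        tic = rng.uniform(0, 5, 500)
        cc = composition_closure(toc, tic)
        ok = ~cc.clipped
        total = cc.carbonates + cc.organic_matter + cc.silicates
        assert np.all(np.abs(total[ok] - 100.0) < 1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            composition_closure(-1.0, 0.0)


class TestComputeFluxes:
    def test_hand_oracle(self, linear_ensemble, small_proxies):
        fe = compute_fluxes(small_proxies, linear_ensemble)
        # rho=0.5 g/cm3, SR=0.1 cm/yr, TOC=2% -> 0.5*0.1*0.02*1e4 = 10
        assert np.allclose(fe.toc_flux, 10.0)
        # (100-2-1)% lithogenic -> 485
        assert np.allclose(fe.l_flux, 485.0)

    def test_zero_toc(self, linear_ensemble, small_proxies):
        rec = small_proxies.assign(toc=0.0)
        fe = compute_fluxes(rec, linear_ensemble)
        assert np.all(fe.toc_flux == 0.0)

    def test_pure_organic_zero_lithogenic(self, linear_ensemble, small_proxies):
        rec = small_proxies.assign(toc=100.0, tic=0.0)
        fe = compute_fluxes(rec, linear_ensemble)
        assert np.all(fe.l_flux == 0.0)

    def test_missing_density_lists_depths(self, linear_ensemble, small_proxies):
        rec = small_proxies.copy()
        rec.loc[1, "density"] = np.nan
        with pytest.raises(DataError, match=r"20"):
            compute_fluxes(rec, linear_ensemble)

    def test_density_fallback(self, linear_ensemble, small_proxies):
        rec = small_proxies.drop(columns=["density"])
        fe = compute_fluxes(rec, linear_ensemble, density_fallback=0.5)
        assert np.allclose(fe.toc_flux, 10.0)

    def test_event_exclusion(self, linear_ensemble, small_proxies):
        rec = small_proxies.assign(event=[False, True, False, False])
        fe = compute_fluxes(rec, linear_ensemble)
        assert fe.depths.size == 3
        fe2 = compute_fluxes(rec, linear_ensemble, exclude_events=False)
        assert fe2.depths.size == 4

    def test_monotone_response_to_sr(self, small_proxies, linear_ensemble):
        # halving all ages doubles SR and both fluxes, proportionally
        faster = AgeDepthEnsemble(
            linear_ensemble.depths, linear_ensemble.ages / 2.0, 2015.0
        )
        fe1 = compute_fluxes(small_proxies, linear_ensemble)
        fe2 = compute_fluxes(small_proxies, faster)
        assert np.allclose(fe2.toc_flux, 2 * fe1.toc_flux)
        assert np.allclose(fe2.l_flux, 2 * fe1.l_flux)

    def test_duplicate_depths_rejected(self, linear_ensemble, small_proxies):
        rec = small_proxies.copy()
        rec.loc[1, "depth"] = 10.0
        with pytest.raises(DataError):
            compute_fluxes(rec, linear_ensemble)


class TestTrapFlux:
    def test_hand_oracle(self):
        assert trap_flux(10, 0.01, 1, 10, 0) == pytest.approx((1000.0, 100.0, 900.0))

    def test_full_closure_zero_lithogenic(self):
        total, toc, lith = trap_flux(5, 0.02, 2, 60, 40)
        assert lith == 0.0

    def test_deployment_proportionality(self):
        one = np.array(trap_flux(10, 0.01, 1, 10, 5))
        two = np.array(trap_flux(10, 0.01, 2, 10, 5))
        assert np.allclose(two, one / 2)

    def test_zero_deployment(self):
        with pytest.raises(ParameterError):
            trap_flux(10, 0.01, 0, 10, 0)


class TestBinning:
    def test_single_member_one_sample_per_bin(self, linear_ensemble, small_proxies):
        fe = compute_fluxes(small_proxies, linear_ensemble)
        centres, mat, occ = bin_flux_ensemble(fe, 100.0, 1500.0, 2000.0)
        filled = occ[:, 0] > 0
        assert np.all(mat[filled, 0] == 10.0)

    def test_constant_series_bin_mean(self):
        ages = np.array([[1900.0, 1910.0, 1950.0, 1960.0]])
        vals = np.array([[3.0, 3.0, 3.0, 3.0]])
        centres, mat, occ = bin_ensemble_series(ages, vals, 50.0, 1900.0, 2000.0)
        assert np.all(mat[np.isfinite(mat)] == 3.0)

    def test_two_samples_mean(self):
        ages = np.array([[1910.0, 1930.0]])
        vals = np.array([[2.0, 4.0]])
        centres, mat, occ = bin_ensemble_series(ages, vals, 50.0, 1900.0, 1950.0)
        assert mat[0, 0] == pytest.approx(3.0)  # oracle: (2+4)/2

    def test_empty_window_errors(self, linear_ensemble, small_proxies):
        fe = compute_fluxes(small_proxies, linear_ensemble)
        with pytest.raises(DataError):
            bin_flux_ensemble(fe, 10.0, 100.0, 200.0)

    def test_bad_parameters(self):
        with pytest.raises(ParameterError):
            bin_ensemble_series(np.zeros((1, 2)), np.zeros(2), -1.0, 0, 10)
        with pytest.raises(ParameterError):
            bin_ensemble_series(np.zeros((1, 2)), np.zeros(2), 1.0, 10, 0)


class TestFluxRecovery:
    def test_constant_flux_recovered(self, fast_settings):
        """Known constant flux: ensemble median within 10% at >=90% of samples."""
        import pandas as pd
        from limnoflux.agemodel import fit_age_model
        from limnoflux.synthetic import simulate_chronology, simulate_dates

        chron = simulate_chronology(20, 5, 10, memory=1.0, acc_shape=1e9, seed=21)
        depths = np.array([10.0, 25.0, 45.0, 65.0, 85.0, 95.0])
        dates = simulate_dates(chron, depths, np.full(6, 4.0), ["calendar"] * 6,
                               seed=22)
        ens = fit_age_model(dates, core_depth=100, settings=fast_settings, seed=23)
        sample_d = np.arange(2.0, 99.0, 2.0)
        rec = pd.DataFrame(
            {"depth": sample_d, "toc": 2.0, "tic": 1.0, "density": 0.5}
        )
        fe = compute_fluxes(rec, ens)
        target = 0.5 * 0.1 * 0.02 * 1e4  # 10 g m-2 yr-1, exactly
        med = np.median(fe.toc_flux, axis=0)
        assert np.mean(np.abs(med - target) / target <= 0.10) >= 0.90


class TestCoreTop:
    def test_mean_over_top_centimetre(self, linear_ensemble):
        import pandas as pd
        from limnoflux.flux import core_top_flux

        rec = pd.DataFrame(
            {"depth": [0.4, 0.8, 5.0, 10.0], "toc": [2.0, 4.0, 2.0, 2.0],
             "tic": [1.0] * 4, "density": [0.5] * 4}
        )
        fe = compute_fluxes(rec, linear_ensemble)
        top = core_top_flux(fe, max_depth=1.0)
        assert top["n_samples"] == 2
        # mean of the two top samples' fluxes (toc 2% and 4% at SR 0.1)
        assert top["toc_flux"] == pytest.approx((10.0 + 20.0) / 2)
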