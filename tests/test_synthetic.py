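import json

import numpy as np
import pytest
from scipy import stats

from limnoflux.calibration import CalibrationCurve
from limnoflux.errors import ParameterError, RangeError, SchemaError
from limnoflux.synthetic import (
    LAKE_DEFAULTS,
    RegimeSpec,
    chronology_from_rate_profile,
    make_transect,
    simulate_chronology,
    simulate_dates,
    simulate_diatoms,
    simulate_proxies,
    write_transect,
)


class TestChronology:
    def test_memory_one_is_linear(self):
        ch = simulate_chronology(10, 5, 12, memory=1.0, seed=0)
        assert np.allclose(ch.section_accumulation, ch.section_accumulation[0])
        ages = ch.age_ce([0, 25, 50])
        slopes = -np.diff(ages) / 25.0
        assert np.allclose(slopes, ch.section_accumulation[0])

    def test_zero_variance_gamma(self):
        ch = simulate_chronology(
            10, 5, 10, acc_shape=1e9, memory=0.0, top_age=2015, seed=1
        )
        assert ch.age_ce(50.0)[0] == pytest.approx(2015 - 500, abs=0.1)

    def test_monotone_age(self):
        for s in range(10):
            ch = simulate_chronology(15, 4, 8, memory=0.5, seed=s)
            ages = ch.age_offset(np.linspace(0, ch.depth_span, 40))
            assert np.all(np.diff(ages) >= 0)

    def test_mean_accumulation_matches_recursion_oracle(self):
        """MC mean of core-average accumulation vs direct recursion oracle."""
        acc_mean, shape, mem, n_sec = 10.0, 1.5, 0.6, 12
        sim = np.array([
            simulate_chronology(n_sec, 5, acc_mean, shape, mem, seed=s)
            .section_accumulation.mean()
            for s in range(1000)
        ])
        # independent oracle: direct Monte-Carlo of the stated recursion
        rng = np.random.default_rng(99_999)
        orc = np.empty(1000)
        for r in range(1000):
            g = rng.gamma(shape, acc_mean / shape, n_sec)
            a = np.empty(n_sec)
            a[0] = g[0]
            for i in range(1, n_sec):
                a[i] = mem * a[i - 1] + (1 - mem) * g[i]
            orc[r] = a.mean()
        se = np.hypot(sim.std(ddof=1), orc.std(ddof=1)) / np.sqrt(1000)
        assert abs(sim.mean() - orc.mean()) <= 2 * se

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            simulate_chronology(0, 5, 10)
        with pytest.raises(ParameterError):
            simulate_chronology(5, 5, -1)

    def test_rate_profile_places_changes(self):
        ch = chronology_from_rate_profile(
            lambda age: 5.0 if age >= 1950 else 20.0, 20, 4, top_age=2015, seed=2
        )
        # upper sections accumulate fast (5 yr/cm) until 1950 is passed
        assert ch.section_accumulation[0] == pytest.approx(5.0)
        assert ch.section_accumulation[-1] == pytest.approx(20.0)


class TestDates:
    def test_noiseless_limit(self):
        ch = simulate_chronology(10, 5, 10, memory=1.0, seed=3)
        d = simulate_dates(ch, [20.0], [1e-9], ["calendar"], seed=4)
        assert d["age"].iloc[0] == pytest.approx(ch.age_ce(20.0)[0], abs=1e-6)

    def test_zscore_mean(self):
        ch = simulate_chronology(10, 5, 10, memory=1.0, seed=5)
        true = ch.age_ce(25.0)[0]
        sigma = 10.0
        draws = simulate_dates(
            ch, [25.0] * 500, [sigma] * 500, ["calendar"] * 500, seed=6
        )["age"].to_numpy()
        z = (draws - true) / sigma
        assert abs(z.mean()) <= 2 / np.sqrt(500)

    def test_depth_out_of_range(self):
        ch = simulate_chronology(10, 5, 10, seed=7)
        with pytest.raises(RangeError):
            simulate_dates(ch, [-1.0], [5.0], ["calendar"], seed=8)

    def test_radiocarbon_through_curve(self):
        ch = simulate_chronology(10, 5, 50, memory=1.0, acc_shape=1e9, seed=9)
        curve = CalibrationCurve.synthetic(lo=-70, hi=4000)
        d = simulate_dates(ch, [40.0], [1e-9], ["radiocarbon"], curve=curve, seed=10)
        true_cal_bp = 1950.0 - ch.age_ce(40.0)[0]
        assert d["age"].iloc[0] == pytest.approx(curve.c14_at(true_cal_bp)[()], abs=1e-5)

    def test_zscores_standard_normal_batches(self):
        """KS vs N(0,1) passes at alpha=0.01 in >=95% of 100 batches of 200."""
        ch = simulate_chronology(10, 5, 10, memory=1.0, seed=11)
        true = ch.age_ce(30.0)[0]
        passed = 0
        for b in range(100):
            draws = simulate_dates(
                ch, [30.0] * 200, [8.0] * 200, ["calendar"] * 200, seed=1000 + b
            )["age"].to_numpy()
            z = (draws - true) / 8.0
            passed += stats.kstest(z, "norm").pvalue > 0.01
        assert passed >= 95


class TestProxies:
    def _chron(self):
        return simulate_chronology(20, 4, 10, memory=1.0, acc_shape=1e9, seed=12)

    def test_constant_when_noiseless(self):
        regs = {"toc": [RegimeSpec("toc", 1950, 2.0, 2.0)]}
        out = simulate_proxies(self._chron(), regs, 2.0, seed=13)
        assert np.allclose(out["toc"], 2.0)

    def test_step_recovery_monte_carlo(self):
        """Mean(post) - mean(pre) ~= configured step within 2 SE over 200 reps."""
        step = 3.0
        diffs = np.empty(200)
        ch = self._chron()
        for r in range(200):
            regs = {"toc": [RegimeSpec("toc", 1950, 2.0, 2.0 + step, noise_sd=0.5)]}
            out = simulate_proxies(ch, regs, 2.0, seed=5000 + r)
            post = out.loc[out["age_true_ce"] >= 1950, "toc"]
            pre = out.loc[out["age_true_ce"] < 1950, "toc"]
            diffs[r] = post.mean() - pre.mean()
        se = diffs.std(ddof=1) / np.sqrt(200)
        assert abs(diffs.mean() - step) <= 2 * se + 1e-9

    def test_unknown_variable_schema_error(self):
        regs = {"mystery": [RegimeSpec("mystery", 1950, 0.0, 1.0)]}
        with pytest.raises(SchemaError):
            simulate_proxies(self._chron(), regs, 2.0, seed=14,
                             known_variables={"toc", "tic"})

    def test_closure_kept_valid(self):
        regs = {
            "toc": [RegimeSpec("toc", 1950, 60.0, 60.0, noise_sd=5.0)],
            "tic": [RegimeSpec("tic", 1950, 50.0, 50.0, noise_sd=5.0)],
        }
        out = simulate_proxies(self._chron(), regs, 2.0, seed=15)
        assert np.all(out["toc"] + out["tic"] <= 100 + 1e-9)

    def test_density_positive(self):
        regs = {"toc": [RegimeSpec("toc", 1950, 1.0, 1.0)]}
        out = simulate_proxies(self._chron(), regs, 2.0, seed=16,
                               density_mean=0.05, density_sd=0.2)
        assert np.all(out["density"] > 0)


class TestDiatoms:
    def _chron(self):
        return simulate_chronology(20, 4, 10, memory=1.0, acc_shape=1e9, seed=17)

    def test_row_sums_exact(self):
        df = simulate_diatoms(self._chron(), 8, [0, 1], 1950, seed=18)
        taxa = [c for c in df.columns if c.startswith(("plank_", "benth_"))]
        assert (df[taxa].sum(axis=1) == 400).all()

    def test_symmetric_limit(self):
        df = simulate_diatoms(
            self._chron(), 5, [], 1950, concentration=1e9,
            valves_per_sample=5000, seed=19,
        )
        taxa = [c for c in df.columns if c.startswith("benth_")]
        rel = df[taxa].to_numpy() / 5000.0
        # multinomial sd ~ sqrt(p(1-p)/n) ~ 0.006
        assert np.all(np.abs(rel - 0.2) < 0.03)

    def test_planktonic_rise(self):
        rises = 0
        for s in range(20):
            df = simulate_diatoms(self._chron(), 10, [0, 1, 2], 1950, seed=s)
            ages = self._chron().age_ce(df["depth"].to_numpy())
            taxa = [c for c in df.columns if c.startswith("plank_")]
            tot = df[[c for c in df.columns if c.startswith(("plank_", "benth_"))]].sum(axis=1)
            share = df[taxa].sum(axis=1) / tot
            rises += share[ages >= 1950].mean() > share[ages < 1950].mean()
        assert rises >= 19

    def test_bad_planktonic_index(self):
        with pytest.raises(ParameterError):
            simulate_diatoms(self._chron(), 5, [7], 1950, seed=20)


class TestTransect:
    def test_sample_counts_in_range(self):
        tr = make_transect(seed=0)
        assert set(tr) == set(LAKE_DEFAULTS)
        for bundle in tr.values():
            assert 38 <= len(bundle["proxies"]) <= 83

    def test_truth_sidecar_roundtrip(self, tmp_path):
        tr = make_transect(seed=0, lakes=["CR", "SA"])
        out = write_transect(tr, tmp_path / "fix")
        truths = json.loads((out / "truth.json").read_text())
        assert truths["CR"]["cp_years"] == [1850.0, 1950.0]
        assert (out / "CR_dates.csv").exists()
        assert (out / "SA_diatoms.csv").exists()

    def test_determinism(self):
        a = make_transect(seed=5, lakes=["CR"])
        b = make_transect(seed=5, lakes=["CR"])
        assert a["CR"]["proxies"].equals(b["CR"]["proxies"])
        assert a["CR"]["dates"].equals(b["CR"]["dates"])

    def test_unknown_lake(self):
        with pytest.raises(ParameterError):
            make_transect(seed=0, lakes=["XX"])

    def test_sa_flux_step_magnitude(self):
        """SA organic flux steps from ~14 to ~66 g m-2 yr-1 at 1970."""
        from limnoflux.agemodel import AgeDepthEnsemble
        from limnoflux.flux import compute_fluxes

        tr = make_transect(seed=3, lakes=["SA"])
        truth = tr["SA"]["truth"]
        bounds = np.array(truth["section_boundaries"])
        acc = np.array(truth["section_accumulation"])
        cum = np.concatenate([[0.0], np.cumsum(np.diff(bounds) * acc)])
        ens = AgeDepthEnsemble(bounds, cum[None, :], 2015.0)
        fe = compute_fluxes(tr["SA"]["proxies"], ens)
        t, v = fe.median_series("toc_flux")
        pre = v[(t >= 1945) & (t < 1968)].mean()
        post = v[(t > 1972) & (t <= 2012)].mean()
        assert pre == pytest.approx(14.0, rel=0.35)
        assert post == pytest.approx(66.0, rel=0.35)
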