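import numpy as np
import pandas as pd
import pytest

from limnoflux.errors import CoverageError, DataError, ParameterError
from limnoflux.ordination import (
    AgeUncertainSeries,
    age_uncertain_pca,
    diatom_summaries,
    filter_taxa,
    hdr_interval,
    hellinger_pca,
    hellinger_transform,
    ppca_missing,
    standardized_pca,
)


def _eig_oracle(X):
    """Independent eigendecomposition of the correlation matrix."""
    vals = np.linalg.eigvalsh(np.corrcoef(X.T))[::-1]
    return vals / vals.sum()


class TestStandardizedPCA:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 30)
        res = standardized_pca(np.column_stack([x, 3 * x + 2]))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_eig_oracle(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        res = standardized_pca(X)
        assert np.allclose(res.variance_fractions, _eig_oracle(X), atol=1e-8)

    def test_orthonormal_loadings(self):
        X = np.random.default_rng(1).normal(size=(25, 4))
        res = standardized_pca(X)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-10)

    def test_zero_variance_column_dropped(self):
        X = np.random.default_rng(2).normal(size=(15, 3))
        X[:, 1] = 4.2
        res = standardized_pca(X, variables=["a", "b", "c"])
        assert res.variables == ["a", "c"]

    def test_missing_values_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            standardized_pca(X)

    def test_variance_fractions_monotone(self):
        X = np.random.default_rng(4).normal(size=(40, 6))
        res = standardized_pca(X)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() <= 1 + 1e-9


class TestHellinger:
    def test_hand_oracle(self):
        out = hellinger_transform(np.array([[9.0, 16.0]]))
        assert np.allclose(out, [[0.6, 0.8]])

    def test_unit_row_sum_of_squares(self):
        counts = np.random.default_rng(5).integers(0, 50, size=(12, 8)) + 1
        H = hellinger_transform(counts)
        assert np.allclose((H**2).sum(axis=1), 1.0, atol=1e-12)

    def test_rare_taxon_excluded(self):
        # 0.5% everywhere stays below the 1% filter
        counts = pd.DataFrame({
            "common": [199, 199, 199],
            "other": [796, 796, 796],
            "rare": [5, 5, 5],
        })
        assert "rare" not in filter_taxa(counts)
        assert "common" in filter_taxa(counts)

    def test_single_occurrence_excluded(self):
        counts = pd.DataFrame({"a": [50, 50, 50], "b": [50, 0, 0]})
        # b exceeds 1% where present but occurs once only
        assert filter_taxa(counts, min_occurrences=2) == ["a"]

    def test_all_filtered_errors(self):
        counts = pd.DataFrame({"a": [1000, 1000], "b": [1, 1]})
        with pytest.raises(DataError):
            hellinger_pca(counts, min_abundance=2.0)

    def test_pca_runs_unstandardized(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(15, 6)),
            columns=[f"t{i}" for i in range(6)],
        )
        res = hellinger_pca(counts)
        assert res.meta["transform"] == "hellinger"
        assert res.variance_fractions[0] > 0


class TestPPCA:
    def test_complete_matches_pca(self):
        X = np.random.default_rng(7).normal(size=(30, 5))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        full = standardized_pca(X)
        pp = ppca_missing(Z, n_components=2, tol=1e-9, max_iter=5000, seed=0)
        assert np.allclose(
            pp.variance_fractions, full.variance_fractions[:2], atol=1e-6
        )

    def test_one_factor_recovery(self):
        rng = np.random.default_rng(8)
        W = rng.normal(size=(6, 1))
        ok = 0
        for s in range(5):
            r = np.random.default_rng(100 + s)
            X = r.normal(size=(100, 1)) @ W.T + r.normal(0, 0.3, size=(100, 6))
            X[r.random((100, 6)) < 0.1] = np.nan
            res = ppca_missing(X, n_components=1, seed=s, max_iter=3000)
            ok += abs(np.corrcoef(res.loadings[:, 0], W[:, 0])[0, 1]) > 0.95
        assert ok >= 4

    def test_all_missing_column(self):
        X = np.random.default_rng(9).normal(size=(10, 3))
        X[:, 2] = np.nan
        with pytest.raises(DataError):
            ppca_missing(X)

    def test_all_missing_row(self):
        X = np.random.default_rng(10).normal(size=(10, 3))
        X[4, :] = np.nan
        with pytest.raises(DataError):
            ppca_missing(X)


class TestHDR:
    def test_shortest_interval(self):
        x = np.concatenate([np.zeros(90), np.full(10, 100.0)])
        lo, hi = hdr_interval(x, 0.5)
        assert (lo, hi) == (0.0, 0.0)

    def test_full_mass(self):
        lo, hi = hdr_interval(np.arange(10.0), 1.0)
        assert (lo, hi) == (0.0, 9.0)

    def test_bad_mass(self):
        with pytest.raises(ParameterError):
            hdr_interval(np.arange(5.0), 1.5)


def _constant_series(name, values, times, n_members=4):
    ages = np.tile(times, (n_members, 1))
    return AgeUncertainSeries(name, ages, values)


class TestAgeUncertainPCA:
    def test_zero_uncertainty_collapses_to_pca(self):
        rng = np.random.default_rng(11)
        times = np.linspace(1000, 2000, 60)
        vals = [np.sin(times / 100) + rng.normal(0, 0.1, 60) for _ in range(3)]
        series = [
            _constant_series(f"v{i}", v, times) for i, v in enumerate(vals)
        ]
        res = age_uncertain_pca(series, 50.0, 1000.0, 2000.0, seed=1)
        # oracle: classical PCA of the binned, standardized matrix
        from limnoflux.flux import bin_ensemble_series

        cols = [
            bin_ensemble_series(times[None, :], v, 50.0, 1000.0, 2000.0)[1][:, 0]
            for v in vals
        ]
        X = np.column_stack(cols)
        keep = np.isfinite(X).all(axis=1)
        ref = standardized_pca(X[keep])
        med = res.score_median[keep, 0]
        assert np.allclose(np.abs(med), np.abs(ref.scores[:, 0]), atol=1e-6)

    def test_single_variable_pc1_is_one(self):
        times = np.linspace(1000, 2000, 50)
        rng = np.random.default_rng(12)
        s = _constant_series("only", rng.normal(size=50), times)
        res = age_uncertain_pca([s], 50.0, 1000.0, 2000.0, seed=2)
        assert np.allclose(res.variance_fractions[:, 0], 1.0, atol=1e-9)

    def test_bands_nested(self):
        rng = np.random.default_rng(13)
        times = np.linspace(1500, 2000, 40)
        series = [
            AgeUncertainSeries(
                f"v{i}",
                times[None, :] + rng.normal(0, 5, (8, 40)),
                rng.normal(size=40),
            )
            for i in range(3)
        ]
        res = age_uncertain_pca(series, 50.0, 1500.0, 2000.0, seed=3)
        fin = np.isfinite(res.hdr50[:, 0, 0])
        assert np.all(res.hdr95[fin, 0, 0] <= res.hdr50[fin, 0, 0] + 1e-12)
        assert np.all(res.hdr95[fin, 0, 1] >= res.hdr50[fin, 0, 1] - 1e-12)

    def test_coverage_error_on_sparse_grid(self):
        times = np.array([1990.0, 2000.0])
        s1 = _constant_series("a", np.array([1.0, 2.0]), times)
        s2 = _constant_series("b", np.array([2.0, 1.0]), times)
        with pytest.raises(CoverageError):
            age_uncertain_pca([s1, s2], 10.0, 1000.0, 2010.0, seed=4)


class TestDiatomSummaries:
    def _counts(self):
        return pd.DataFrame(
            {
                "depth": [1.0, 2.0],
                "plank_0": [100, 250],
                "benth_1": [200, 50],
                "cysts": [30, 0],
                "microspheres": [100, 150],
                "spike": [100000, 100000],
                "mass_g": [0.1, 0.1],
            }
        )

    def test_concentration_hand_oracle(self):
        out = diatom_summaries(self._counts())
        # 300 valves * (1e5 spike / 100 spheres) / 0.1 g = 3.0e6
        assert out["valves_per_g"].iloc[0] == pytest.approx(3.0e6)

    def test_zero_cysts(self):
        out = diatom_summaries(self._counts())
        assert out["cd_ratio"].iloc[1] == 0.0

    def test_relative_abundances_sum_to_one(self):
        out = diatom_summaries(self._counts())
        rel = out[[c for c in out.columns if c.startswith("rel_")]]
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_planktonic_fraction(self):
        out = diatom_summaries(self._counts(), planktonic=["plank_0"])
        assert out["planktonic_fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_unknown_planktonic_taxon(self):
        with pytest.raises(ParameterError):
            diatom_summaries(self._counts(), planktonic=["missing"])

    def test_zero_microspheres(self):
        c = self._counts()
        c.loc[0, "microspheres"] = 0
        with pytest.raises(DataError):
            diatom_summaries(c)
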