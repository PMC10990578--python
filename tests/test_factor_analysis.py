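import numpy as np
import pandas as pd
import pytest

from audioscene.factor_analysis import (EFAResult, SingularCorrelationError,
                                        align_loadings, bartlett_sphericity,
                                        fit_efa, kmo, loading_table,
                                        parallel_analysis,
                                        simulate_pa_quantiles)
from audioscene.synthetic_data import planted_factor_data, standardized_loadings

TWO_FACTOR = np.array([[0.8, 0.0], [0.8, 0.0], [0.7, 0.0], [0.7, 0.0],
                       [0.0, 0.8], [0.0, 0.8], [0.0, 0.7], [0.0, 0.7]])


class TestKmo:
    def test_strong_common_factor_is_adequate(self, rng):
        loadings = np.full((8, 1), 0.8)
        data = planted_factor_data(loadings, 0.4, 500, rng)
        assert kmo(data) > 0.7

    def test_independent_variables_near_half(self, rng):
        vals = [kmo(rng.normal(size=(300, 6))) for _ in range(30)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_matches_partial_correlation_oracle(self, rng):
        # oracle: partial correlations by OLS residualization
        data = planted_factor_data(np.array([[0.7], [0.6], [0.5], [0.6]]),
                                   0.6, 120, rng)
        z = (data - data.mean(0)) / data.std(0)
        p = z.shape[1]
        r = np.corrcoef(z, rowvar=False)
        q = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                others = [k for k in range(p) if k not in (i, j)]
                xo = z[:, others]
                beta_i = np.linalg.lstsq(xo, z[:, i], rcond=None)[0]
                beta_j = np.linalg.lstsq(xo, z[:, j], rcond=None)[0]
                ri = z[:, i] - xo @ beta_i
                rj = z[:, j] - xo @ beta_j
                q[i, j] = q[j, i] = np.corrcoef(ri, rj)[0, 1]
        off = ~np.eye(p, dtype=bool)
        expected = np.sum(r[off] ** 2) / (np.sum(r[off] ** 2) +
                                          np.sum(q[off] ** 2))
        assert kmo(data) == pytest.approx(expected, abs=1e-6)

    def test_singular_matrix_rejected(self, rng):
        x = rng.normal(size=(50, 2))
        data = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises((SingularCorrelationError, np.linalg.LinAlgError)):
            kmo(data)


class TestBartlett:
    def test_df_formula_for_eight_variables(self, rng):
        chi2, df, p = bartlett_sphericity(rng.normal(size=(100, 8)))
        assert df == 28

    def test_closed_form_on_sample_correlation(self, rng):
        data = planted_factor_data(np.array([[0.7], [0.7], [0.7]]), 0.7,
                                   100, rng)
        chi2, df, _ = bartlett_sphericity(data)
        r = np.corrcoef(data, rowvar=False)
        n, p = data.shape
        expected = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(r))
        assert chi2 == pytest.approx(expected, rel=1e-9)
        assert df == 3

    def test_duplicated_column_rejected(self, rng):
        x = rng.normal(size=(60, 1))
        data = np.column_stack([x, x, rng.normal(size=(60, 1))])
        with pytest.raises(SingularCorrelationError):
            bartlett_sphericity(data)


class TestParallelAnalysis:
    def test_independent_noise_suggests_zero(self, rng):
        q = simulate_pa_quantiles(200, 8, n_sims=500, seed=0)
        hits = sum(parallel_analysis(rng.normal(size=(200, 8)),
                                     sim_quantiles=q).suggested_n == 0
                   for _ in range(50))
        assert hits >= 47

    def test_planted_two_factor_design_detected(self, rng):
        q = simulate_pa_quantiles(200, 8, n_sims=500, seed=0)
        hits = sum(parallel_analysis(
            planted_factor_data(TWO_FACTOR, 0.5, 200, rng),
            sim_quantiles=q).suggested_n == 2 for _ in range(50))
        assert hits >= 47

    def test_suggestion_non_increasing_in_noise(self, rng):
        q = simulate_pa_quantiles(200, 8, n_sims=500, seed=0)
        means = []
        for noise in (0.4, 1.2, 3.0):
            vals = [parallel_analysis(
                planted_factor_data(TWO_FACTOR, noise, 200, rng),
                sim_quantiles=q).suggested_n for _ in range(20)]
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_seeded_determinism(self, rng):
        data = rng.normal(size=(100, 5))
        a = parallel_analysis(data, n_sims=200, seed=42)
        b = parallel_analysis(data, n_sims=200, seed=42)
        assert np.allclose(a.sim_quantiles, b.sim_quantiles)
        assert a.suggested_n == b.suggested_n


class TestFitEfa:
    def test_planted_two_factor_recovery(self, rng):
        data = planted_factor_data(TWO_FACTOR, 0.5, 400, rng)
        target = standardized_loadings(TWO_FACTOR, 0.5)
        res = fit_efa(data, 2)
        aligned, _, _ = align_loadings(res.loadings.to_numpy(), target)
        assert np.max(np.abs(aligned - target)) < 0.1

    def test_single_factor_variance_accounting(self, rng):
        loadings = np.array([[0.8], [0.7], [0.6], [0.75], [0.65]])
        # unit-variance observed variables: standardize loadings
        comm = loadings.ravel() ** 2 / (loadings.ravel() ** 2 + 0.5**2)
        data = planted_factor_data(loadings, 0.5, 600, rng)
        res = fit_efa(data, 1)
        aligned, _, _ = align_loadings(res.loadings.to_numpy(),
                                       np.sqrt(comm)[:, None])
        assert np.max(np.abs(aligned.ravel() - np.sqrt(comm))) < 0.1
        assert res.total_variance == pytest.approx(comm.mean(), abs=0.08)

    def test_orthogonal_factors_stay_uncorrelated(self, rng):
        data = planted_factor_data(TWO_FACTOR, 0.5, 500, rng)
        res = fit_efa(data, 2)
        assert abs(res.factor_corr[0, 1]) < 0.1

    def test_correlated_factors_recovered(self, rng):
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        data = planted_factor_data(TWO_FACTOR, 0.4, 800, rng, factor_corr=phi)
        res = fit_efa(data, 2)
        assert res.factor_corr[0, 1] == pytest.approx(0.5, abs=0.15)


class TestLoadingTable:
    @staticmethod
    def result_of(loadings):
        df = pd.DataFrame(loadings,
                          index=[f"v{i}" for i in range(len(loadings))],
                          columns=[f"F{j+1}" for j in range(len(loadings[0]))])
        k = df.shape[1]
        return EFAResult(loadings=df, factor_corr=np.eye(k),
                         variance_share=np.full(k, 0.3), total_variance=0.6,
                         n_factors=k, rotation="oblimin", kmo=0.7,
                         bartlett=(100.0, 28, 0.0))

    def test_threshold_blanks_and_shows(self):
        table, flags = loading_table(self.result_of([[0.39, 0.9],
                                                     [-0.43, 0.1]]))
        assert np.isnan(table.loc["v0", "F1"])   # 0.39 below |.40|
        assert table.loc["v1", "F1"] == pytest.approx(-0.43)
        assert flags == []

    def test_empty_factor_flagged(self):
        table, flags = loading_table(self.result_of([[0.8, 0.2], [0.7, 0.3]]))
        assert flags == ["F2"]

    def test_rows_ordered_by_dominant_factor_then_magnitude(self):
        table, _ = loading_table(self.result_of([[0.5, 0.0], [0.0, 0.9],
                                                 [0.8, 0.0]]))
        assert list(table.index) == ["v2", "v0", "v1"]


class TestAlignLoadings:
    def test_permutation_and_sign_recovered(self, rng):
        target = TWO_FACTOR + rng.normal(0, 0.01, TWO_FACTOR.shape)
        scrambled = -target[:, ::-1]
        aligned, perm, signs = align_loadings(scrambled, target)
        assert np.max(np.abs(aligned - target)) < 1e-9
        assert list(perm) == [1, 0]
        assert list(signs) == [-1.0, -1.0]
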