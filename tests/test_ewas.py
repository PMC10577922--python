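"""Design construction, moderated fitting, inflation, and q-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from acewas.config import CohortConfig, MethylomeConfig
from acewas.core import MethylationMatrix, deconvolve_cohort
from acewas.ewas import (
    build_design,
    compute_vif,
    fit_moderated,
    genomic_lambda,
    squeeze_variances,
    storey_qvalues,
)
from acewas.synthetic import simulate_cohort, simulate_methylome


def _toy_matrix(values, toy_annotation, positions=None, scale="M"):
    values = np.asarray(values, dtype=float)
    pos = positions if positions is not None else 100 * (1 + np.arange(values.shape[0]))
    ann = toy_annotation(pos)
    return MethylationMatrix(values, scale, ann, [f"S{i}" for i in range(values.shape[1])])


class TestDesign:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame(
            {"Intercept": 1.0, "a": [1, -1, 1, -1], "b": [1, 1, -1, -1]}, dtype=float
        )
        vif = compute_vif(X)
        assert vif["a"] == pytest.approx(1.0)
        assert vif["b"] == pytest.approx(1.0)

    def test_duplicated_predictor_infinite_vif(self):
        X = pd.DataFrame({"Intercept": 1.0, "a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        vif = compute_vif(X)
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_vif_matches_statsmodels_regression_oracle(self, cohort):
        design = build_design(cohort, "individual", cell_proportions=None)
        X = design.matrix
        col = "total_aces" if "total_aces" in X else X.columns[-1]
        j = list(X.columns).index(col)
        others = X.drop(columns=[col])
        r2 = sm.OLS(X[col], others).fit().rsquared
        assert design.vif[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)

    def test_copula_cohort_vif_bounded(self):
        cohort = simulate_cohort(CohortConfig(n_samples=5000, seed=13))
        design = build_design(cohort, "individual")
        assert np.isfinite(design.vif).all()
        assert design.vif.max() < 10

    def test_exposure_column_sets(self, cohort):
        assert build_design(cohort, "total_linear").exposure_columns == ["total_aces"]
        assert build_design(cohort, "total_categorical").exposure_columns == ["ace_1_3", "ace_4_10"]
        assert len(build_design(cohort, "individual").exposure_columns) == 10

    def test_shared_covariate_columns_across_specs(self, cohort):
        d1 = build_design(cohort, "total_linear")
        d2 = build_design(cohort, "individual")
        assert d1.covariate_columns == d2.covariate_columns

    def test_constant_column_rejected(self, cohort):
        c = cohort.copy()
        c["total_aces"] = 2
        with pytest.raises(ValueError, match="total_aces"):
            build_design(c, "total_linear")


class TestModeratedFit:
    def test_single_cpg_equals_ols(self, cohort, toy_annotation):
        rng = np.random.default_rng(3)
        design = build_design(cohort, "total_linear")
        X = design.matrix
        y = rng.normal(size=len(X))
        matrix = _toy_matrix(y[None, :], toy_annotation)
        matrix.sample_ids = list(X.index)
        res = fit_moderated(matrix, design)
        fit = sm.OLS(y, X.to_numpy()).fit()
        j = list(X.columns).index("total_aces")
        row = res.table.iloc[0]
        assert row["coef"] == pytest.approx(fit.params[j], rel=1e-10)
        assert row["t"] == pytest.approx(fit.tvalues[j], rel=1e-8)
        assert row["p"] == pytest.approx(fit.pvalues[j], rel=1e-6)
        assert res.d0 == 0.0

    def test_homoscedastic_limit_equals_pooled_t(self, cohort, toy_annotation):
        # identical residual variance at every CpG: d0 -> inf, pooled t
        rng = np.random.default_rng(4)
        design = build_design(cohort, "total_linear")
        X = design.matrix.to_numpy()
        n = X.shape[0]
        base = rng.normal(size=n)
        Y = np.tile(base, (100, 1))
        matrix = _toy_matrix(Y, toy_annotation)
        matrix.sample_ids = list(design.matrix.index)
        res = fit_moderated(matrix, design)
        assert np.isinf(res.d0)
        fit = sm.OLS(base, X).fit()
        j = list(design.matrix.columns).index("total_aces")
        pooled_t = fit.params[j] / (np.sqrt(fit.mse_resid) * np.sqrt(np.linalg.pinv(X.T @ X)[j, j]))
        np.testing.assert_allclose(res.table["t"].to_numpy(), pooled_t, rtol=1e-8)

    def test_coefficients_identical_to_ols(self, cohort, null_methylome):
        matrix, reference, _ = null_methylome
        cell = deconvolve_cohort(matrix, reference)
        design = build_design(cohort, "total_linear", cell_proportions=cell)
        res = fit_moderated(matrix, design)
        Y = matrix.to_m().values
        X = design.matrix.to_numpy()
        ols = Y @ (np.linalg.pinv(X.T @ X) @ X.T).T
        np.testing.assert_allclose(res.coefficients.to_numpy(), ols, rtol=1e-10)

    def test_null_type_one_error_calibrated(self, cohort, null_methylome):
        matrix, reference, truth = null_methylome
        cell = deconvolve_cohort(matrix, reference)
        design = build_design(cohort, "total_linear", cell_proportions=cell)
        res = fit_moderated(matrix, design)
        frac = (res.table["p"] < 0.05).mean()
        # binomial 99.9% band at m = 1500
        assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / 1500) < frac < 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / 1500)

    def test_variance_shrinkage_recovers_prior(self):
        # s^2 drawn from the scaled-F sampling model: moment matching should
        # recover the generating prior df and scale
        rng = np.random.default_rng(8)
        d0_true, s0_true, d = 6.0, 1.5, 190
        m = 20000
        s2 = s0_true * d0_true / rng.chisquare(d0_true, size=m)
        s2 = s2 * rng.chisquare(d, size=m) / d
        post, d0, s0 = squeeze_variances(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_planted_dmp_detected_at_q05(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort = simulate_cohort(CohortConfig(seed=100 + seed))
            cfg = MethylomeConfig(n_cpgs=1000, seed=200 + seed,
                                  planted_dmps=[(5, "total_aces", 1.0)])
            matrix, reference, truth = simulate_methylome(cohort, cfg)
            cell = deconvolve_cohort(matrix, reference)
            res = fit_moderated(matrix, build_design(cohort, "total_linear", cell_proportions=cell))
            planted_id = truth.effects["cpg_id"].iloc[0]
            q = res.table.set_index("cpg_id").loc[planted_id, "q"]
            hits += q <= 0.05
        assert hits >= 0.8 * n_seeds


class TestLambdaAndQvalues:
    def test_lambda_one_at_null_median(self):
        assert genomic_lambda(np.full(11, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_lambda_null_simulation(self):
        rng = np.random.default_rng(0)
        p = stats.chi2.sf(rng.chisquare(1, size=100_000), 1)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.01)

    def test_lambda_tracks_inflation(self):
        rng = np.random.default_rng(2)
        chi = 1.5 * rng.chisquare(1, size=200_000)
        p = stats.chi2.sf(chi, 1)
        assert genomic_lambda(p) == pytest.approx(1.5, rel=0.01)

    def test_lambda_input_validation(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.array([]))
        with pytest.raises(ValueError):
            genomic_lambda(np.array([0.0, 0.5]))

    def test_bh_cummin_example(self):
        q, pi0 = storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0_method="fixed_1")
        assert pi0 == 1.0
        np.testing.assert_allclose(q, 0.04)

    def test_single_p_identity(self):
        q, _ = storey_qvalues(np.array([0.03]), pi0_method="fixed_1")
        assert q[0] == pytest.approx(0.03)

    def test_uniform_pi0_near_one(self):
        ok = 0
        for seed in range(10):
            p = np.random.default_rng(seed).uniform(size=10_000)
            _, pi0 = storey_qvalues(p)
            ok += 0.9 <= pi0 <= 1.0
        assert ok >= 9

    def test_pi0_one_dominates_smaller_pi0(self):
        p = np.random.default_rng(5).uniform(size=5000) ** 2
        q1, _ = storey_qvalues(p, pi0_method="fixed_1")
        qs, pi0 = storey_qvalues(p)
        assert pi0 <= 1.0
        assert (q1 >= qs - 1e-12).all()
        assert (qs <= 1.0).all()
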