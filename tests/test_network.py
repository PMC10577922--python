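"""Co-methylation networks: TOM, modules, eigengenes, trait tests, q-values."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from acewas.ewas import bh_fdr
from acewas.network import (
    _eigengene,
    detect_modules,
    grenander_qvalues,
    me_trait_tests,
    module_eigengenes,
    pick_soft_power,
    tom_from_adjacency,
    tom_matrix,
)


def _block_data(seed=0, n=196, block_sizes=(60, 60), noise=80, within_r=0.8):
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_r)
    blocks = [
        lam * rng.normal(size=n) + np.sqrt(1 - lam**2) * rng.normal(size=(s, n))
        for s in block_sizes
    ]
    blocks.append(rng.normal(size=(noise, n)))
    truth = np.concatenate(
        [np.full(s, chr(ord("A") + i)) for i, s in enumerate(block_sizes)]
        + [np.full(noise, "grey")]
    )
    return np.vstack(blocks), truth


class TestTom:
    def test_isolated_perfect_pair(self):
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        T = tom_from_adjacency(A)
        assert T[0, 1] == pytest.approx(1.0)

    def test_three_node_hand_computed(self):
        A = np.array([[0.0, 1.0, 0.5], [1.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        T = tom_from_adjacency(A)
        assert T[0, 1] == pytest.approx((0.25 + 1.0) / (1.5 + 1.0 - 1.0), abs=1e-10)

    def test_symmetric_bounded_unit_diagonal(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(40, 50))
        T = tom_matrix(M, 6)
        np.testing.assert_allclose(T, T.T)
        assert (T >= 0).all() and (T <= 1).all()
        np.testing.assert_allclose(np.diag(T), 1.0)

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            tom_matrix(np.random.default_rng(0).normal(size=(5, 10)), 0.5)

    def test_constant_row_rejected(self):
        M = np.random.default_rng(0).normal(size=(5, 10))
        M[2] = 3.0
        with pytest.raises(ValueError, match="constant"):
            tom_matrix(M, 2)


class TestSoftPower:
    def test_heterogeneous_factor_network_passes_threshold(self):
        # heterogeneous loadings give an approximately scale-free
        # connectivity distribution; the smallest passing power is returned
        rng = np.random.default_rng(7)
        n, m = 200, 400
        f = rng.normal(size=n)
        lam = rng.uniform(0.2, 0.95, size=m) ** 1.5
        M = lam[:, None] * f + np.sqrt(1 - lam[:, None] ** 2) * rng.normal(size=(m, n))
        power, fits = pick_soft_power(M)
        assert fits[power] >= 0.8
        assert power == min(p for p in fits if fits[p] >= 0.8)

    def test_single_candidate_returned(self):
        M = np.random.default_rng(2).normal(size=(50, 60))
        power, fits = pick_soft_power(M, candidates=(6,))
        assert power == 6
        assert set(fits) == {6}

    def test_equicorrelated_blocks_take_fallback_branch(self, caplog):
        # a two-point connectivity distribution is far from scale-free, so
        # no power passes and the best-R^2 fallback fires with a warning
        import logging

        M, _ = _block_data(seed=3, block_sizes=(100, 100), noise=0)
        with caplog.at_level(logging.WARNING):
            power, fits = pick_soft_power(M)
        assert max(fits.values()) < 0.8
        assert fits[power] == max(fits.values())
        assert any("no candidate" in r.message for r in caplog.records)

    def test_deterministic(self):
        M, _ = _block_data(seed=5)
        assert pick_soft_power(M) == pick_soft_power(M)


class TestModules:
    def test_planted_blocks_recovered(self):
        M, truth = _block_data(seed=0)
        tom = tom_matrix(M, 6)
        labels = detect_modules(tom, M, min_size=30)
        assert adjusted_rand_score(truth, labels) >= 0.9
        noise_labels = labels[120:]
        assert (noise_labels == "grey").mean() > 0.8

    def test_undersized_block_absorbed_into_grey(self):
        M, _ = _block_data(seed=1, block_sizes=(29,), noise=100)
        tom = tom_matrix(M, 6)
        labels = detect_modules(tom, M, min_size=30)
        assert (labels == "grey").all()

    def test_single_block_one_module(self):
        M, _ = _block_data(seed=2, block_sizes=(60,), noise=0)
        tom = tom_matrix(M, 6)
        labels = detect_modules(tom, M, min_size=30)
        mods = [m for m in pd.unique(labels) if m != "grey"]
        assert len(mods) == 1
        assert (labels == mods[0]).sum() == 60


class TestEigengenes:
    def test_rank_one_module(self):
        base = np.random.default_rng(0).normal(size=50)
        M = np.tile(base, (30, 1))
        labels = np.full(30, "M1", dtype=object)
        ms = module_eigengenes(M, labels, [f"S{i}" for i in range(50)])
        assert ms.variance_explained["M1"] == pytest.approx(100.0)
        np.testing.assert_allclose(ms.kme.to_numpy(), 1.0, atol=1e-10)

    def test_anticorrelated_pair_signs(self):
        x = np.random.default_rng(1).normal(size=40)
        M = np.vstack([x, -x])
        ms = module_eigengenes(M, np.array(["M1", "M1"], dtype=object), [f"S{i}" for i in range(40)])
        assert ms.variance_explained["M1"] == pytest.approx(100.0)
        kme = np.sort(ms.kme.to_numpy())
        np.testing.assert_allclose(kme, [-1.0, 1.0], atol=1e-10)

    def test_factor_share_matches_spectral_oracle(self):
        rng = np.random.default_rng(2)
        n, m, lam = 400, 60, 0.8
        f = rng.normal(size=n)
        M = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=(m, n))
        ms = module_eigengenes(M, np.full(m, "M1", dtype=object), [f"S{i}" for i in range(n)])
        # oracle: top-eigenvalue share of the sample correlation matrix
        Z = (M - M.mean(1, keepdims=True)) / M.std(1, keepdims=True)
        evals = np.linalg.eigvalsh(Z @ Z.T / n)
        share = 100.0 * evals[-1] / evals.sum()
        assert ms.variance_explained["M1"] == pytest.approx(share, rel=0.02)

    def test_eigengene_unit_variance_and_sign_convention(self):
        M, _ = _block_data(seed=3, block_sizes=(40,), noise=0)
        labels = np.full(40, "M1", dtype=object)
        ms = module_eigengenes(M, labels, [f"S{i}" for i in range(M.shape[1])])
        e = ms.eigengenes["M1"].to_numpy()
        assert e.std() == pytest.approx(1.0)
        # flipping all module CpGs flips kME but not |kME| or variance
        ms2 = module_eigengenes(-M, labels, [f"S{i}" for i in range(M.shape[1])])
        assert ms2.variance_explained["M1"] == pytest.approx(ms.variance_explained["M1"])
        np.testing.assert_allclose(np.abs(ms2.kme), np.abs(ms.kme), atol=1e-10)

    def test_sex_chromosome_modules_excluded(self):
        M, _ = _block_data(seed=4, block_sizes=(40, 40), noise=0)
        labels = np.array(["M1"] * 40 + ["M2"] * 40, dtype=object)
        chroms = np.array(["chrX"] * 40 + ["chr2"] * 40)
        ms = module_eigengenes(M, labels, [f"S{i}" for i in range(M.shape[1])], chroms=chroms)
        assert ms.excluded_sex_modules == ["M1"]
        assert list(ms.eigengenes.columns) == ["M2"]


class TestGrenander:
    def test_uniform_eta0_near_one(self):
        ok = 0
        for seed in range(10):
            _, eta0 = grenander_qvalues(np.random.default_rng(seed).uniform(size=10_000))
            ok += 0.9 <= eta0 <= 1.0
        assert ok >= 9

    def test_enriched_p_beats_bh(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.beta(0.2, 8, 5000), rng.uniform(size=5000)])
        q, eta0 = grenander_qvalues(p)
        assert eta0 < 0.8
        i = np.argmin(p)
        assert q[i] < bh_fdr(p)[i]

    def test_all_ones_boundary(self):
        q, eta0 = grenander_qvalues(np.ones(20))
        np.testing.assert_allclose(q, 1.0)
        assert eta0 == 1.0

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            grenander_qvalues(np.array([0.1, 0.2]))


class TestMeTraitTests:
    def test_trait_identical_to_eigengene(self, cohort, null_methylome):
        matrix, _, _ = null_methylome
        M = matrix.to_m().values[:200]
        labels = detect_modules(tom_matrix(M, 4), M, min_size=20)
        if not (labels != "grey").any():
            labels[:30] = "M1"
        ms = module_eigengenes(M, labels, matrix.sample_ids)
        mod = ms.eigengenes.columns[0]
        c = cohort.copy()
        c["total_aces"] = ms.eigengenes[mod].to_numpy()
        table = me_trait_tests(ms, c, "total_linear")
        row = table[(table["module"] == mod) & (table["trait"] == "total_aces")].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["p_bivariate"] < 1e-100

    def test_adjusted_equals_bivariate_under_orthogonality(self, cohort):
        # covariates orthogonal to both trait and eigengene leave the slope
        # unchanged (partialled-regression identity)
        rng = np.random.default_rng(6)
        n = len(cohort)
        me = pd.DataFrame({"M1": rng.normal(size=n)}, index=cohort.index)
        from acewas.network import ModuleSet

        ms = ModuleSet(labels=np.array(["M1"] * 10, dtype=object), power=6, eigengenes=me)
        table = me_trait_tests(ms, cohort, "total_linear")
        row = table.iloc[0]
        x = cohort["total_aces"].to_numpy().astype(float)
        y = me["M1"].to_numpy()
        biv_slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        # with simulated independent covariates the adjusted slope is close
        # to, not exactly, the bivariate slope
        assert row["coef_adjusted"] == pytest.approx(biv_slope, abs=0.05)
        assert table.attrs["fdr_method"] == "bh"

    def test_individual_family_uses_grenander(self, cohort):
        rng = np.random.default_rng(8)
        n = len(cohort)
        me = pd.DataFrame(
            {f"M{i}": rng.normal(size=n) for i in range(3)}, index=cohort.index
        )
        from acewas.network import ModuleSet

        ms = ModuleSet(labels=np.array([], dtype=object), power=6, eigengenes=me)
        table = me_trait_tests(ms, cohort, "individual")
        assert len(table) == 30
        assert table.attrs["fdr_method"] == "grenander"
        assert set(["coef_mutual", "p_mutual"]).issubset(table.columns)
        assert table["p_mutual"].notna().all()

    def test_null_traits_uniform_p(self, cohort):
        rng = np.random.default_rng(9)
        n = len(cohort)
        pvals = []
        me = pd.DataFrame({"M1": rng.normal(size=n)}, index=cohort.index)
        from scipy import stats as ss

        for _ in range(1000):
            t = rng.normal(size=n)
            r, p = ss.pearsonr(t, me["M1"].to_numpy())
            pvals.append(p)
        ks = ss.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
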