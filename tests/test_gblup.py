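"""GRM construction, spectral REML vs grid oracle, BLUP vs Henderson's equations."""

import numpy as np
import pytest

from gars.gblup import (
    KinshipMatrix,
    compute_grm,
    predict_gebv,
    predict_gebv_oos,
    reml_fit,
)
from gars.genotype_data import GenotypeDataset, SnpRecord
from oracles import gls_beta, mme_blup, mme_blup_missing, reml_grid_argmax, restricted_loglik_direct


def dataset_from(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snps = [SnpRecord(f"s{j}", 1, 100 * (j + 1)) for j in range(m)]
    return GenotypeDataset([f"i{i}" for i in range(n)], snps, dosage)


def random_psd_kinship(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n + 2))
    K = A @ A.T / (n + 2)
    return KinshipMatrix(K, [f"i{i}" for i in range(n)])


class TestGrm:
    def test_single_snp_hand_values(self):
        """One SNP, dosages (0, 2): centred Z = (-1, 1), denominator 0.5."""
        k = compute_grm(dataset_from([[0.0], [2.0]]))
        np.testing.assert_allclose(k.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_duplicate_individuals_equal_rows(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(5, 40)).astype(float)
        d[4] = d[0]
        k = compute_grm(dataset_from(d)).matrix
        np.testing.assert_allclose(k[4], k[0], atol=1e-12)
        np.testing.assert_allclose(k[:, 4], k[:, 0], atol=1e-12)

    def test_rows_sum_to_zero_and_symmetric(self):
        rng = np.random.default_rng(2)
        k = compute_grm(dataset_from(rng.binomial(2, 0.4, size=(6, 10)))).matrix
        np.testing.assert_allclose(k @ np.ones(6), 0.0, atol=1e-10)
        np.testing.assert_allclose(k, k.T, atol=1e-12)

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(dataset_from(np.full((4, 3), 2.0)))

    def test_diagonal_mean_near_one_plus_mean_freq_factor(self):
        """VanRaden-1 diagonal averages ~1 on unrelated HWE individuals."""
        rng = np.random.default_rng(3)
        f = rng.uniform(0.05, 0.5, size=5000)
        d = rng.binomial(2, f, size=(500, 5000)).astype(float)
        k = compute_grm(dataset_from(d)).matrix
        assert np.mean(np.diag(k)) == pytest.approx(1.0, abs=0.1)


class TestRemlFit:
    def toy(self, seed=0, n=5):
        rng = np.random.default_rng(seed)
        k = random_psd_kinship(n, seed + 100)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        return y, X, k

    def test_matches_grid_oracle_on_toy(self):
        y, X, k = self.toy(seed=4)
        fit = reml_fit(y, X, k)
        h2_star, ll_star = reml_grid_argmax(y, X, k.matrix)
        assert abs(fit.h2 - h2_star) <= 1.5e-3  # within one 0.001 grid cell
        assert fit.reml_loglik >= ll_star - 1e-6

    def test_loglik_formula_consistent_with_direct_route(self):
        y, X, k = self.toy(seed=9, n=8)
        fit = reml_fit(y, X, k)
        assert fit.reml_loglik == pytest.approx(
            restricted_loglik_direct(fit.h2, y, X, k.matrix), abs=1e-6
        )

    def test_h2_recovery_simulation(self):
        """Mean REML h2 over seeds close to the simulated truth (h2 = 0.5)."""
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = rng.binomial(2, rng.uniform(0.1, 0.5, 800), size=(300, 800)).astype(float)
            geno = dataset_from(d)
            k = compute_grm(geno)
            eff = rng.normal(size=800) * np.sqrt(1.0 / 800)
            g = (d - d.mean(0)) @ eff
            e = rng.normal(size=300) * g.std()
            fit = reml_fit(g + e, np.ones((300, 1)), k)
            ests.append(fit.h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_exact_fixed_effect_fit_flagged_degenerate(self):
        n = 6
        k = random_psd_kinship(n, 11)
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ np.array([1.0, 2.0])  # zero residual after fixed effects
        fit = reml_fit(y, X, k)
        assert fit.degenerate

    def test_zero_variance_phenotype_raises(self):
        k = random_psd_kinship(5, 12)
        with pytest.raises(ValueError, match="variance"):
            reml_fit(np.ones(5), np.ones((5, 1)), k)


class TestPredictGebv:
    def test_vu_zero_gives_zeros(self):
        k = random_psd_kinship(4, 0)
        u = predict_gebv(np.arange(4.0), np.ones((4, 1)), k, 0.0, 1.0, np.array([0.0]))
        np.testing.assert_array_equal(u, np.zeros(4))

    def test_matches_henderson_mme(self):
        """BLUP from the covariance form equals Henderson's MME solution (n = 4)."""
        n, vu, ve = 4, 1.3, 0.7
        rng = np.random.default_rng(21)
        k = random_psd_kinship(n, 22)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        beta_mme, u_mme = mme_blup(y, X, k.matrix, vu, ve)
        V = vu * k.matrix + ve * np.eye(n)
        beta = gls_beta(y, X, V)
        np.testing.assert_allclose(beta, beta_mme, atol=1e-8)
        u = predict_gebv(y, X, k, vu, ve, beta)
        np.testing.assert_allclose(u, u_mme, atol=1e-6)

    def test_identity_kinship_small_ve_returns_residual(self):
        n = 5
        rng = np.random.default_rng(30)
        k = KinshipMatrix(np.eye(n), [f"i{i}" for i in range(n)])
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        beta = np.array([y.mean()])
        u = predict_gebv(y, X, k, 1.0, 1e-10, beta)
        np.testing.assert_allclose(u, y - y.mean(), atol=1e-6)

    def test_blup_orthogonal_to_gls_projected_design(self):
        """V^-1-weighted cross-product of GEBVs with X vanishes at the GLS fit."""
        n, vu, ve = 7, 0.9, 1.1
        rng = np.random.default_rng(31)
        k = random_psd_kinship(n, 32)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        V = vu * k.matrix + ve * np.eye(n)
        beta = gls_beta(y, X, V)
        r = y - X @ beta
        np.testing.assert_allclose(X.T @ np.linalg.solve(V, r), 0.0, atol=1e-8)


class TestPredictOos:
    def test_matches_mme_with_missing_records(self):
        """4 train / 2 test toy equals the missing-record MME breeding values."""
        n, vu, ve = 6, 1.1, 0.6
        rng = np.random.default_rng(40)
        k = random_psd_kinship(n, 41)
        train, test = np.array([0, 1, 2, 3]), np.array([4, 5])
        X_train = np.column_stack([np.ones(4), rng.normal(size=4)])
        y_train = rng.normal(size=4)
        V_tt = vu * k.submatrix(train, train) + ve * np.eye(4)
        beta = gls_beta(y_train, X_train, V_tt)
        beta_mme, u_mme = mme_blup_missing(y_train, X_train, train, k.matrix, vu, ve)
        np.testing.assert_allclose(beta, beta_mme, atol=1e-8)

        class FakeFit:
            pass

        fit = FakeFit()
        fit.vu, fit.ve, fit.beta_fixed = vu, ve, beta
        u_test = predict_gebv_oos(train, test, y_train, X_train, k, fit)
        np.testing.assert_allclose(u_test, u_mme[test], atol=1e-6)

    def test_duplicate_of_training_individual_matches(self):
        """A test individual genetically identical to a training one gets its GEBV."""
        rng = np.random.default_rng(50)
        d = rng.binomial(2, 0.4, size=(6, 120)).astype(float)
        d[5] = d[0]  # test duplicate of train individual 0
        geno = dataset_from(d)
        k = compute_grm(geno)
        train, test = np.arange(5), np.array([5])
        y_train = (d[:5] - d[:5].mean(0)).sum(axis=1) / 10.0
        X_train = np.ones((5, 1))
        fit = reml_fit(y_train, X_train, KinshipMatrix(k.submatrix(train, train), [f"i{i}" for i in range(5)]))
        u_test = predict_gebv_oos(train, test, y_train, X_train, k, fit)
        assert u_test[0] == pytest.approx(fit.gebv[0], abs=1e-6)

    def test_overlap_raises_and_vu_zero(self):
        k = random_psd_kinship(4, 60)

        class FakeFit:
            vu, ve = 0.0, 1.0
            beta_fixed = np.array([0.0])

        with pytest.raises(ValueError, match="overlap"):
            predict_gebv_oos([0, 1], [1, 2], np.zeros(2), np.ones((2, 1)), k, FakeFit())
        u = predict_gebv_oos([0, 1], [2, 3], np.zeros(2), np.ones((2, 1)), k, FakeFit())
        np.testing.assert_array_equal(u, np.zeros(2))
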