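"""Gibbs samplers: reproducibility, null behavior, prediction contracts.

The closed-form oracle equivalences (BLUP / ridge) at full chain lengths
live in the acceptance suite; here shorter chains exercise the same code
paths plus the contracts around masking and the ordinal response.
"""

import numpy as np
import pytest

import svpredict as sv
from svpredict.bayes import standardize_design
from svpredict.containers import KernelMatrix

from conftest import hwe_snp_panel


@pytest.fixture(scope="module")
def gaussian_kernel_problem():
    G = hwe_snp_panel(n=120, m=400, seed=3)
    K = sv.additive_grm(G)
    rng = np.random.default_rng(4)
    g = np.linalg.cholesky(K.values + 1e-8 * np.eye(K.n)) @ rng.standard_normal(K.n)
    y = g + rng.normal(0, 1.0, K.n)
    return K, y


SHORT = sv.MCMCSettings(n_iter=2500, burn_in=500, thin=2, seed=1)


class TestFitRkhs:
    def test_null_phenotype_gives_null_genetic_values(self):
        K = KernelMatrix(np.eye(60), "additive")
        spec = sv.KernelRegressionSpec([K], fixed_variances=([1.0], 1.0))
        s = sv.fit_rkhs(np.zeros(60), spec, sv.MCMCSettings(8000, 1000, 1, seed=2))
        assert np.abs(s.genetic_values).max() < 0.05

    def test_seed_reproducibility(self, gaussian_kernel_problem):
        K, y = gaussian_kernel_problem
        spec = sv.KernelRegressionSpec([K])
        a = sv.fit_rkhs(y, spec, SHORT)
        b = sv.fit_rkhs(y, spec, SHORT)
        assert np.array_equal(a.genetic_values, b.genetic_values)
        assert a.variance_means == b.variance_means
        c = sv.fit_rkhs(y, spec, sv.MCMCSettings(2500, 500, 2, seed=99))
        assert not np.array_equal(a.genetic_values, c.genetic_values)

    def test_sample_count_matches_settings(self, gaussian_kernel_problem):
        K, y = gaussian_kernel_problem
        s = sv.fit_rkhs(y, sv.KernelRegressionSpec([K]), SHORT)
        assert s.n_samples == SHORT.n_samples
        assert len(s.variance_samples["residual"]) == s.n_samples

    def test_doubling_chain_keeps_posterior_means(self, gaussian_kernel_problem):
        """Twice the sweeps moves posterior means by no more than twice the
        Monte-Carlo standard error of the genetic values."""
        K, y = gaussian_kernel_problem
        spec = sv.KernelRegressionSpec([K])
        s1 = sv.fit_rkhs(y, spec, sv.MCMCSettings(4000, 1000, 1, seed=11))
        s2 = sv.fit_rkhs(y, spec, sv.MCMCSettings(8000, 1000, 1, seed=12))
        resid_sd = np.sqrt(s1.variance_means["residual"])
        mc_se = resid_sd / np.sqrt(s1.n_samples / 10.0)  # ~10x autocorrelation slack
        assert np.mean(np.abs(s1.genetic_values - s2.genetic_values)) < 2 * mc_se

    def test_masked_rows_are_predicted_not_fit(self, gaussian_kernel_problem):
        K, y = gaussian_kernel_problem
        mask = np.zeros(K.n, dtype=bool)
        mask[:20] = True
        s = sv.fit_rkhs(y, sv.KernelRegressionSpec([K]), SHORT, mask=mask)
        preds = sv.predict(s)
        assert preds.shape == (20,)
        with pytest.raises(ValueError, match="not masked"):
            sv.predict(s, indices=[25])

    def test_empty_mask_prediction_set(self, gaussian_kernel_problem):
        K, y = gaussian_kernel_problem
        s = sv.fit_rkhs(y, sv.KernelRegressionSpec([K]), SHORT)
        assert sv.predict(s).size == 0

    def test_ordinal_probabilities_in_unit_interval(self, gaussian_kernel_problem):
        K, y = gaussian_kernel_problem
        z = (y > np.median(y)).astype(float)
        mask = np.zeros(K.n, dtype=bool)
        mask[-15:] = True
        spec = sv.KernelRegressionSpec([K], response="ordinal")
        s = sv.fit_rkhs(z, spec, SHORT, mask=mask)
        p = sv.predict(s)
        assert np.all((p > 0) & (p < 1))
        # masked true classes were never read: flipping them changes nothing
        z2 = z.copy()
        z2[-15:] = 1 - z2[-15:]
        s2 = sv.fit_rkhs(z2, spec, SHORT, mask=mask)
        assert np.array_equal(sv.predict(s), sv.predict(s2))

    def test_all_masked_errors(self):
        K = KernelMatrix(np.eye(10), "additive")
        with pytest.raises(ValueError, match="masked"):
            sv.fit_rkhs(np.zeros(10), sv.KernelRegressionSpec([K]), SHORT,
                        mask=np.ones(10, dtype=bool))

    def test_non_psd_kernel_rejected(self):
        bad = KernelMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), "additive")
        with pytest.raises(ValueError, match="PSD"):
            sv.fit_rkhs(np.zeros(2), sv.KernelRegressionSpec([bad]), SHORT)

    def test_prediction_invariant_to_accession_permutation(self):
        """Relabeling accessions permutes the predictions (up to MC error)."""
        G = hwe_snp_panel(n=80, m=300, seed=6)
        K = sv.additive_grm(G)
        rng = np.random.default_rng(7)
        y = rng.normal(size=80) + np.diag(K.values) * 0.5
        mask = np.zeros(80, dtype=bool)
        mask[:10] = True
        settings = sv.MCMCSettings(12000, 2000, 1, seed=8)
        s1 = sv.fit_rkhs(y, sv.KernelRegressionSpec([K]), settings, mask=mask)
        perm = rng.permutation(80)
        Kp = KernelMatrix(K.values[np.ix_(perm, perm)], "additive")
        s2 = sv.fit_rkhs(y[perm], sv.KernelRegressionSpec([Kp]), settings,
                         mask=mask[perm])
        back = np.empty(80)
        back[perm] = s2.eta_mean
        assert np.abs(back - s1.eta_mean).max() < 0.06


class TestFitBayesC:
    def test_null_pi_concentrates_near_prior_mean(self):
        """With y independent of X the posterior inclusion stays at the
        prior level and no marker looks confidently associated."""
        rng = np.random.default_rng(21)
        X, _, _ = standardize_design(rng.binomial(2, 0.4, size=(150, 200)).astype(float))
        y = rng.normal(size=150)
        s = sv.fit_bayesc(y, sv.BayesCSpec(X), SHORT)
        assert s.inclusion_probs.max() < 0.5
        assert s.pi_mean < 0.05

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(22)
        X, _, _ = standardize_design(rng.binomial(2, 0.4, size=(80, 60)).astype(float))
        y = rng.normal(size=80)
        a = sv.fit_bayesc(y, sv.BayesCSpec(X), SHORT)
        b = sv.fit_bayesc(y, sv.BayesCSpec(X), SHORT)
        assert np.array_equal(a.effect_means, b.effect_means)
        assert np.array_equal(a.inclusion_probs, b.inclusion_probs)

    def test_constant_column_rejected(self):
        X = np.ones((30, 3))
        with pytest.raises(ValueError, match="constant"):
            standardize_design(X)
        Xok, _, _ = standardize_design(np.random.default_rng(0).normal(size=(30, 3)))
        Xbad = Xok.copy()
        Xbad[:, 1] = 0.0
        with pytest.raises(ValueError, match="constant"):
            sv.fit_bayesc(np.zeros(30), sv.BayesCSpec(Xbad), SHORT)

    def test_ordinal_predictions_bounded(self):
        rng = np.random.default_rng(23)
        X, _, _ = standardize_design(rng.binomial(2, 0.4, size=(100, 50)).astype(float))
        beta = np.zeros(50)
        beta[:5] = 1.5
        z = ((X @ beta + rng.normal(size=100)) > 0).astype(float)
        mask = np.zeros(100, dtype=bool)
        mask[:12] = True
        s = sv.fit_bayesc(z, sv.BayesCSpec(X, response="ordinal"), SHORT, mask=mask)
        p = sv.predict(s)
        assert np.all((p > 0) & (p < 1))

    def test_inclusion_probabilities_are_probabilities(self):
        rng = np.random.default_rng(24)
        X, _, _ = standardize_design(rng.binomial(2, 0.4, size=(60, 40)).astype(float))
        s = sv.fit_bayesc(rng.normal(size=60), sv.BayesCSpec(X), SHORT)
        assert np.all((s.inclusion_probs >= 0) & (s.inclusion_probs <= 1))
        assert s.n_samples == SHORT.n_samples


class TestSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            sv.MCMCSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            sv.MCMCSettings(n_iter=100, burn_in=10, thin=0)

    def test_paper_and_test_scales(self):
        paper = sv.MCMCSettings.paper_scale()
        assert (paper.n_iter, paper.burn_in, paper.thin) == (100_000, 500, 5)
        test = sv.MCMCSettings.test_scale()
        assert test.n_iter < paper.n_iter

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sv.KernelRegressionSpec([])
        with pytest.raises(ValueError):
            sv.BayesCSpec(np.zeros((3, 2)), pi0=0.0)
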