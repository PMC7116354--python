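import numpy as np
import pytest
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

import gwasprio as gp
from gwasprio import enrichment
from gwasprio.enrichment import EstimationError, LocalFdrFit, _kkt_violation

from conftest import make_eqclasses


class TestProbitTransform:
    def test_reference_values(self, toy):
        stats = toy["stats"].subset(np.arange(3))
        stats.p[:] = [0.5, 1 - norm.cdf(2.0), 1e-320]
        z = gp.pvalues_to_zscores(stats).z
        assert z[0] == pytest.approx(0.0, abs=1e-12)
        assert z[1] == pytest.approx(2.0, abs=1e-9)
        assert z[2] == 38.0  # clamp keeps the transform finite

    def test_domain_error(self, toy):
        stats = toy["stats"].subset(np.arange(2))
        stats.p[0] = 0.0
        with pytest.raises(ValueError):
            gp.pvalues_to_zscores(stats)


class TestLocalFdr:
    def test_pure_null_gives_high_lfdr(self):
        z = np.random.default_rng(7).standard_normal(50_000)
        fit = gp.estimate_mppa(z)
        assert fit.pi0 >= 0.95
        assert np.median(fit.lfdr) >= 0.95
        assert np.all((fit.lfdr >= 0) & (fit.lfdr <= 1))

    def test_mixture_separates_posteriors(self):
        rng = np.random.default_rng(8)
        M = 50_000
        delta = rng.random(M) < 0.10
        z = rng.standard_normal(M)
        z[delta] += 3.0
        fit = gp.estimate_mppa(z)
        assert fit.mppa[z > 4].mean() > fit.mppa[z < 1].mean()
        # oracle: exact two-group posterior with known components
        exact = 0.1 * norm.pdf(z, 3, 1) / (0.1 * norm.pdf(z, 3, 1)
                                           + 0.9 * norm.pdf(z))
        assert np.corrcoef(fit.mppa, exact)[0, 1] > 0.99
        assert np.mean(np.abs(fit.mppa - exact)) < 0.05

    def test_upper_tail_monotone_after_cleanup(self):
        rng = np.random.default_rng(9)
        z = np.r_[rng.standard_normal(20_000), rng.normal(3, 1, 2_000)]
        fit = gp.estimate_mppa(z)
        upper = z > 0
        order = np.argsort(z[upper])
        assert np.all(np.diff(fit.lfdr[upper][order]) <= 1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(EstimationError):
            gp.estimate_mppa(np.zeros(2000))

    def test_small_sample_warns_but_runs(self, caplog):
        z = np.random.default_rng(1).standard_normal(500)
        with caplog.at_level("WARNING", logger="gwasprio.enrichment"):
            fit = gp.estimate_mppa(z)
        assert any("unstable" in r.message for r in caplog.records)
        assert np.all((fit.lfdr >= 0) & (fit.lfdr <= 1))


class TestClassMeanMppa:
    def _fit_with(self, mppa):
        mppa = np.asarray(mppa, float)
        return LocalFdrFit(1.0, np.zeros(1), np.zeros(1), 1 - mppa, mppa)

    def test_mean_and_singleton_and_clip(self):
        eq = make_eqclasses([[1], [0], [1]], None, [2, 1, 1])
        fit = self._fit_with([0.2, 0.4, 0.9, 1.0])
        eq = gp.class_mean_mppa(eq, fit)
        assert eq.psibar[0] == pytest.approx(0.3)
        assert eq.psibar[1] == pytest.approx(0.9)
        assert eq.psibar[2] == 1 - 1e-6  # clipped away from 1


class TestPriorModel:
    def test_lambda_max_shrinks_everything(self, toy_reweight):
        eq = toy_reweight.eqclasses
        lmax = gp.lambda_max(eq)
        for lam in (lmax, 2 * lmax):
            m = gp.fit_prior_model(eq, lam)
            assert np.all(m.beta == 0)
            assert np.allclose(m.class_priors, m.class_priors[0])

    def test_no_signal_annotation_gets_zero_coefficient(self):
        eq = make_eqclasses([[1], [0]], [0.3, 0.3], [50, 50])
        for lam in (0.0, 0.5, 5.0):
            m = gp.fit_prior_model(eq, lam)
            assert m.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_logistic_identity_of_fitted_priors(self, toy_reweight):
        m = toy_reweight.prior_model
        eq = toy_reweight.eqclasses
        pred = expit(np.asarray(eq.V_classes @ m.beta).ravel() + m.kappa)
        assert np.max(np.abs(m.class_priors - pred)) < 1e-12

    def test_two_class_closed_form_at_lambda_zero(self, two_class_eq):
        m = gp.fit_prior_model(two_class_eq, 0.0)
        assert m.kappa == pytest.approx(logit(0.2), abs=1e-6)
        assert m.beta[0] == pytest.approx(logit(0.7) - logit(0.2), abs=1e-6)

    def test_unpenalized_fit_matches_statsmodels_glm(self):
        rng = np.random.default_rng(3)
        V = (rng.random((8, 3)) < 0.4).astype(np.int8)
        psibar = np.clip(rng.random(8), 0.05, 0.95)
        sizes = rng.integers(5, 50, 8)
        eq = make_eqclasses(V, psibar, sizes)
        m = gp.fit_prior_model(eq, 0.0)
        glm = sm.GLM(psibar, sm.add_constant(V.astype(float)),
                     family=sm.families.Binomial(), var_weights=sizes).fit()
        assert np.allclose(np.r_[m.kappa, m.beta], glm.params, atol=1e-6)

    def test_recovery_from_logistic_truth(self):
        # psibar generated exactly from logistic(-3 + 1.5 * V1), K = 5
        rng = np.random.default_rng(5)
        V = (rng.random((32, 5)) < 0.5).astype(np.int8)
        psibar = expit(-3.0 + 1.5 * V[:, 0])
        eq = make_eqclasses(V, psibar, np.full(32, 10_000))
        m = gp.fit_prior_model(eq, 1e-6 * gp.lambda_max(eq))
        assert m.beta[0] == pytest.approx(1.5, abs=0.2)
        assert np.all(np.abs(m.beta[1:]) < 0.05)

    def test_kkt_conditions_along_path(self, toy_reweight):
        eq = toy_reweight.eqclasses
        lambdas = enrichment.default_lambda_path(eq, n_lambda=10)
        X = np.column_stack([np.ones(eq.n_classes), eq.V_classes.toarray()])
        for m in gp.fit_prior_path(eq, lambdas):
            viol = _kkt_violation(X, eq.sizes.astype(float), eq.psibar,
                                  np.r_[m.kappa, m.beta], m.lam, 0.0)
            assert viol < 1e-4 * max(1.0, eq.sizes.sum())

    def test_bit_reproducible(self, toy_reweight):
        eq = toy_reweight.eqclasses
        lam = 0.3 * gp.lambda_max(eq)
        m1 = gp.fit_prior_model(eq, lam)
        m2 = gp.fit_prior_model(eq, lam)
        assert m1.kappa == m2.kappa and np.array_equal(m1.beta, m2.beta)


class TestPriorPath:
    def test_singleton_path_equals_single_fit(self, toy_reweight):
        eq = toy_reweight.eqclasses
        lam = 0.2 * gp.lambda_max(eq)
        (m_path,) = gp.fit_prior_path(eq, [lam])
        m_single = gp.fit_prior_model(eq, lam)
        assert m_path.kappa == pytest.approx(m_single.kappa, abs=1e-8)
        assert np.allclose(m_path.beta, m_single.beta, atol=1e-8)

    def test_path_starts_empty_and_grows_weakly(self, toy_reweight):
        eq = toy_reweight.eqclasses
        models = gp.fit_prior_path(eq, enrichment.default_lambda_path(eq, n_lambda=40))
        nnz = [m.n_nonzero for m in models]
        assert nnz[0] == 0  # first entry is lambda_max
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))

    def test_increasing_sequence_rejected(self, toy_reweight):
        with pytest.raises(ValueError):
            gp.fit_prior_path(toy_reweight.eqclasses, [0.1, 0.2])


class TestAlternativeModel:
    def test_point_mass(self):
        z = np.array([3.0, 3.0, 0.5, -1.0])
        psi = np.array([1.0, 1.0, 0.0, 0.0])
        alt = gp.estimate_alternative(z, psi)
        assert alt.mu == pytest.approx(3.0) and alt.tau2 == 0.0

    def test_null_snps_with_zero_weight_do_not_matter(self):
        rng = np.random.default_rng(2)
        z = rng.normal(4, 1.5, 100)
        psi = rng.random(100)
        a1 = gp.estimate_alternative(z, psi)
        z2 = np.r_[z, rng.standard_normal(500)]
        psi2 = np.r_[psi, np.zeros(500)]
        a2 = gp.estimate_alternative(z2, psi2)
        assert a1.mu == pytest.approx(a2.mu) and a1.tau2 == pytest.approx(a2.tau2)

    def test_moment_recovery_with_exact_posteriors(self):
        # truths z ~ N(4, 2); weights are the exact two-group posteriors
        rng = np.random.default_rng(9)
        M = 50_000
        delta = rng.random(M) < 0.1
        z = rng.standard_normal(M)
        z[delta] = rng.normal(4, np.sqrt(2), delta.sum())
        f1 = norm.pdf(z, 4, np.sqrt(2))
        psi = 0.1 * f1 / (0.1 * f1 + 0.9 * norm.pdf(z))
        alt = gp.estimate_alternative(z, psi)
        assert alt.mu == pytest.approx(4.0, abs=0.3)
        assert 1 + alt.tau2 == pytest.approx(2.0, abs=0.5)

    def test_all_zero_weights_fall_back(self):
        alt = gp.estimate_alternative(np.arange(5, dtype=float), np.zeros(5))
        assert (alt.mu, alt.tau2) == (2.0, 0.0)


def test_single_em_step_barely_moves_the_intercept():
    """One EM refinement from the two-step estimates changes kappa little on
    well-specified synthetic data (the two-step fit is one EM step from a
    valid start, so a further step should be near a fixed point)."""
    rng = np.random.default_rng(123)
    M, K = 50_000, 5
    V = (rng.random((M, K)) < 0.15).astype(np.int8)
    pi = expit(-3.0 + 1.5 * V[:, 0])
    delta = rng.random(M) < pi
    z = rng.standard_normal(M)
    z[delta] += 4.0
    from gwasprio.mapping import AnnotationMatrix, collapse_equivalence_classes
    annot = AnnotationMatrix(sp.csr_matrix(V), [f"A{k}" for k in range(K)],
                             np.array([f"s{j}" for j in range(M)], object))
    eq = collapse_equivalence_classes(annot)
    lf = gp.estimate_mppa(z)
    eq1 = gp.class_mean_mppa(eq, lf)
    lam = 1e-3 * gp.lambda_max(eq1)
    m = gp.fit_prior_model(eq1, lam)
    alt = gp.estimate_alternative(z, lf.mppa)
    prior = m.predict_prior(V)
    f1, f0 = norm.pdf(z, alt.mu, alt.sd), norm.pdf(z)
    psi_em = prior * f1 / (prior * f1 + (1 - prior) * f0)
    tot = np.bincount(eq.class_of_snp, weights=psi_em, minlength=eq.n_classes)
    eq2 = eq.with_psibar(np.clip(tot / eq.sizes, 1e-6, 1 - 1e-6))
    m_em = gp.fit_prior_model(eq2, lam)
    assert abs(m_em.kappa - m.kappa) < 0.5
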