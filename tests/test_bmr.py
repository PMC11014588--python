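"""Bayesian model reduction / averaging tests against conjugate and
high-precision oracles."""

import numpy as np
import pytest

from structec.bmr import (
    GridSpec,
    STRONG_EVIDENCE_THRESHOLD,
    bma_average,
    bmr_gaussian,
    enumerate_regimes,
    log_bayes_factor,
    score_grid,
    update_subjects,
)
from structec.errors import EmptyGridError, ImproperReductionError, MisalignedParametersError
from structec.gaussian import GaussianDensity
from structec.invert import DCMPosterior, linear_gaussian_evidence
from structec.peb import PriorVarianceTransform, UNINFORMED, build_prior_covariance, invert_group, stack_subject_means

from test_peb import make_posterior


def random_gaussian(rng, d, scale=1.0):
    A = rng.standard_normal((d, d))
    cov = scale * (A @ A.T / d + 0.1 * np.eye(d))
    return GaussianDensity(rng.standard_normal(d), cov)


class TestBmrGaussian:
    def test_identity_reduction_exact(self, rng):
        d = 4
        prior = random_gaussian(rng, d)
        post = random_gaussian(rng, d, 0.3)
        res = bmr_gaussian(prior, post, prior, full_free_energy=-12.3)
        assert res.delta_free_energy == 0.0
        assert np.allclose(res.reduced_posterior.mean, post.mean, atol=1e-12)
        assert res.reduced_free_energy == -12.3

    def test_matches_conjugate_evidence_difference(self, rng):
        """BMR's free-energy change equals the exact log-evidence
        difference between two priors, across 25 random linear-Gaussian
        models of dimension <= 6."""
        for _ in range(25):
            d = rng.integers(1, 7)
            N = d + int(rng.integers(1, 5))
            X = rng.standard_normal((N, d))
            noise_cov = np.diag(rng.uniform(0.3, 1.2, N))
            full_prior = GaussianDensity(0.2 * rng.standard_normal(d), np.diag(rng.uniform(0.3, 2.0, d)))
            reduced_prior = GaussianDensity(0.2 * rng.standard_normal(d), np.diag(rng.uniform(0.05, 1.0, d)))
            theta = full_prior.mean + np.sqrt(np.diag(full_prior.cov)) * rng.standard_normal(d)
            y = X @ theta + np.sqrt(np.diag(noise_cov)) * rng.standard_normal(N)
            post_full, ev_full = linear_gaussian_evidence(X, y, full_prior, noise_cov)
            post_red, ev_red = linear_gaussian_evidence(X, y, reduced_prior, noise_cov)
            res = bmr_gaussian(full_prior, post_full, reduced_prior, ev_full)
            assert res.delta_free_energy == pytest.approx(ev_red - ev_full, abs=1e-6)
            assert res.reduced_free_energy == pytest.approx(ev_red, abs=1e-6)
            assert np.allclose(res.reduced_posterior.mean, post_red.mean, atol=1e-6)
            assert np.allclose(res.reduced_posterior.cov, post_red.cov, atol=1e-6)

    def test_dogmatic_reduction_prunes_parameter(self, rng):
        """Shrinking one parameter's reduced prior variance to 1e-8 drives
        its posterior to the prior mean."""
        d = 3
        X = np.eye(d)
        full_prior = GaussianDensity(np.zeros(d), np.eye(d))
        y = np.array([1.5, -0.7, 0.9])
        post, ev = linear_gaussian_evidence(X, y, full_prior, 0.1 * np.eye(d))
        rv = np.array([1.0, 1e-8, 1.0])
        reduced_prior = GaussianDensity(np.zeros(d), np.diag(rv))
        res = bmr_gaussian(full_prior, post, reduced_prior)
        assert abs(res.reduced_posterior.mean[1]) < 1e-3
        assert abs(res.reduced_posterior.mean[0] - post.mean[0]) < 1e-6

    def test_improper_reduction_raises(self):
        prior = GaussianDensity(np.zeros(1), np.array([[1.0]]))
        post = GaussianDensity(np.zeros(1), np.array([[2.0]]))  # "posterior" wider than prior
        reduced = GaussianDensity(np.zeros(1), np.array([[10.0]]))
        with pytest.raises(ImproperReductionError):
            bmr_gaussian(prior, post, reduced)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(MisalignedParametersError):
            bmr_gaussian(random_gaussian(rng, 2), random_gaussian(rng, 3), random_gaussian(rng, 2))


class TestEnumerateRegimes:
    def test_degenerate_single_point_grid(self):
        spec = GridSpec(alpha_points=1, alpha_range=(0.5, 0.5), beta_points=1)
        regimes = enumerate_regimes(spec)
        assert len(regimes) == 1
        assert regimes[0].alpha == 0.5 and regimes[0].beta == 0.0

    def test_constraints_hold(self):
        regimes = enumerate_regimes(GridSpec())
        assert all(t.alpha >= 0 for t in regimes)
        assert all(t.alpha + t.beta >= 1e-5 for t in regimes)
        assert all(t.beta >= 0 for t in regimes)
        assert all(t.alpha + t.beta <= 0.5 + 1e-12 for t in regimes)

    def test_count_matches_bruteforce_5x5(self):
        spec = GridSpec(alpha_points=5, beta_points=5)
        regimes = enumerate_regimes(spec)
        count = 0
        for a in np.linspace(-0.5, 0.5, 5):
            hi = 0.5 - a
            betas = np.linspace(0.0, hi, 5) if hi > 0 else np.array([0.0])
            for b in betas:
                if a >= 0 and a + b >= 1e-5:
                    count += 1
        assert len(regimes) == count

    def test_default_grid_size(self):
        # 30 equidistant alphas in [-1/2, 1/2]: 15 are nonnegative; 14 of
        # them pair with 30 betas in [0, 1/2 - alpha], and at alpha = 1/2
        # the beta range collapses to {0}
        assert len(enumerate_regimes(GridSpec())) == 14 * 30 + 1

    def test_empty_grid_raises(self):
        with pytest.raises(EmptyGridError):
            enumerate_regimes(GridSpec(alpha_points=1, alpha_range=(-0.5, -0.5), beta_points=1))


@pytest.fixture
def group_setup(rng):
    """Synthetic group model inverted under the uninformed prior, with a
    structure-scaled truth."""
    n, S = 3, 12
    w = rng.uniform(0, 1, (n, n))
    ct = (w + w.T) / 2
    np.fill_diagonal(ct, 0.0)
    ct /= ct.max()
    var = 0.3 * ct + 0.02
    a2 = np.sqrt(var) * rng.standard_normal((n, n))
    np.fill_diagonal(a2, 0.0)
    mats = [a2 + 0.08 * rng.standard_normal((n, n)) for _ in range(S)]
    model = stack_subject_means([make_posterior(n, m) for m in mats])
    peb = invert_group(model)
    full_prior = build_prior_covariance(np.zeros((n, n)), UNINFORMED)
    return peb, full_prior, ct


class TestScoreGrid:
    def test_identity_regime_scores_zero(self, group_setup):
        peb, full_prior, ct = group_setup
        Fk = score_grid(peb, full_prior, ct, [UNINFORMED])
        assert Fk[0] == 0.0

    def test_permutation_equivariance(self, group_setup, rng):
        peb, full_prior, ct = group_setup
        regimes = enumerate_regimes(GridSpec(alpha_points=5, beta_points=5))
        Fk = score_grid(peb, full_prior, ct, regimes)
        perm = rng.permutation(len(regimes))
        Fk_p = score_grid(peb, full_prior, ct, [regimes[i] for i in perm])
        assert np.allclose(Fk[perm], Fk_p)

    def test_structure_scaled_truth_prefers_beta_positive(self, rng):
        """When the truth is generated with beta > 0, the best regime has
        beta > 0 in at least 90% of seeded replicates."""
        wins = 0
        K = 20
        regimes = enumerate_regimes(GridSpec(alpha_points=10, beta_points=10))
        for rep in range(K):
            r = np.random.default_rng(1000 + rep)
            n, S = 6, 16
            w = r.uniform(0, 1, (n, n))
            ct = (w + w.T) / 2
            np.fill_diagonal(ct, 0.0)
            ct /= ct.max()
            a2 = np.sqrt(0.25 * ct + 0.02) * r.standard_normal((n, n))
            np.fill_diagonal(a2, 0.0)
            mats = [a2 + 0.08 * r.standard_normal((n, n)) for _ in range(S)]
            model = stack_subject_means([make_posterior(n, m) for m in mats])
            peb = invert_group(model)
            full_prior = build_prior_covariance(np.zeros((n, n)), UNINFORMED)
            Fk = score_grid(peb, full_prior, ct, regimes)
            if regimes[int(np.argmax(Fk))].beta > 0:
                wins += 1
        assert wins >= 0.9 * K


class TestBmaAverage:
    def test_uniform_weights_give_arithmetic_mean(self):
        regimes = [PriorVarianceTransform(0.1, 0.1), PriorVarianceTransform(0.3, 0.2)]
        res = bma_average(np.zeros(2), regimes)
        assert res.alpha_bar == pytest.approx(0.2)
        assert res.beta_bar == pytest.approx(0.15)

    def test_winner_take_all(self):
        regimes = [PriorVarianceTransform(0.1, 0.0), PriorVarianceTransform(0.4, 0.1)]
        res = bma_average(np.array([0.0, 50.0]), regimes)
        assert res.alpha_bar == pytest.approx(0.4, abs=1e-8)
        assert res.beta_bar == pytest.approx(0.1, abs=1e-8)

    def test_shift_invariance(self, rng):
        regimes = enumerate_regimes(GridSpec(alpha_points=4, beta_points=4))
        Fk = rng.standard_normal(len(regimes)) * 10
        r1 = bma_average(Fk, regimes)
        r2 = bma_average(Fk + 1234.5, regimes)
        assert np.max(np.abs(r1.weights - r2.weights)) < 1e-12

    def test_weights_match_high_precision_softmax(self, rng):
        """Softmax weights agree with a 50-digit-precision computation."""
        from sympy import Float, exp as sexp

        regimes = [PriorVarianceTransform(0.05 * k, 0.01 * k) for k in range(1, 11)]
        Fk = rng.standard_normal(10) * 30
        res = bma_average(np.array(Fk), regimes)
        vals = [sexp(Float(f, 50)) for f in Fk]
        total = sum(vals)
        expect = np.array([float(v / total) for v in vals])
        assert np.allclose(res.weights, expect, atol=1e-14)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_average_in_convex_hull(self, rng):
        regimes = enumerate_regimes(GridSpec(alpha_points=6, beta_points=6))
        Fk = rng.standard_normal(len(regimes))
        res = bma_average(Fk, regimes)
        alphas = [t.alpha for t in regimes]
        betas = [t.beta for t in regimes]
        assert min(alphas) <= res.alpha_bar <= max(alphas)
        assert min(betas) <= res.beta_bar <= max(betas)

    def test_envelope_brackets_point_estimate(self, rng):
        regimes = enumerate_regimes(GridSpec(alpha_points=6, beta_points=6))
        Fk = rng.standard_normal(len(regimes))
        res = bma_average(Fk, regimes)
        mid = res.beta_bar * res.envelope_c + res.alpha_bar
        assert np.all(res.envelope_lo <= mid + 1e-9)
        assert np.all(mid <= res.envelope_hi + 1e-9)


class TestLogBayesFactor:
    def test_basic_identities(self):
        assert log_bayes_factor(5.0, 5.0) == 0.0
        assert log_bayes_factor(8.0, 5.0) == 3.0
        assert log_bayes_factor(5.0, 8.0) == -log_bayes_factor(8.0, 5.0)
        assert STRONG_EVIDENCE_THRESHOLD == 3.0
        # a log-Bayes factor of 3 is about twenty-fold evidence
        assert np.exp(3.0) == pytest.approx(20.0, rel=0.005)


class TestUpdateSubjects:
    def _subject(self, rng, n=2):
        from structec.invert import dcm_parameter_names

        names = dcm_parameter_names(n)
        d = len(names)
        prior = GaussianDensity(np.zeros(d), np.eye(d) * 0.5, tuple(names))
        mean = 0.3 * rng.standard_normal(d)
        cov = np.eye(d) * 0.05
        post = DCMPosterior(GaussianDensity(mean, cov, tuple(names)), free_energy=-5.0, iterations=1, converged=True)
        return prior, post

    def test_identity_empirical_prior_is_noop(self, rng):
        from structec.invert import a_block_names

        n = 2
        prior, post = self._subject(rng, n)
        idx = post.posterior.index_of(a_block_names(n))
        group = prior.marginal(idx)  # group posterior equal to the subject prior on the A-block
        out = update_subjects([prior], [post], group)
        q, F = out[0]
        assert np.allclose(q.mean, post.posterior.mean, atol=1e-12)
        assert F == pytest.approx(post.free_energy)

    def test_dominant_empirical_prior_pins_subjects(self, rng):
        from structec.invert import a_block_names

        n = 2
        g = np.array([0.3, -0.2, 0.1, 0.4])
        group = GaussianDensity(g, np.eye(4) * 1e-8, tuple(a_block_names(n)))
        for _ in range(3):
            prior, post = self._subject(rng, n)
            (q, _), = update_subjects([prior], [post], group)
            idx = q.index_of(a_block_names(n))
            assert np.max(np.abs(q.mean[idx] - g)) < 1e-3

    def test_matches_direct_reinversion_on_linear_toy(self, rng):
        """Updated posteriors equal direct conjugate re-inversion under
        the empirical prior, on a 2-subject linear-Gaussian toy."""
        from structec.invert import a_block_names, dcm_parameter_names

        n = 2
        names = tuple(dcm_parameter_names(n))
        d = len(names)
        block = a_block_names(n)
        X = np.eye(d)
        noise = 0.2 * np.eye(d)
        prior = GaussianDensity(np.zeros(d), np.eye(d) * 0.4, names)
        group = GaussianDensity(0.2 * rng.standard_normal(4), np.diag(rng.uniform(0.02, 0.1, 4)), tuple(block))
        for _ in range(2):
            y = rng.standard_normal(d)
            post_g, ev = linear_gaussian_evidence(X, y, prior, noise)
            post = DCMPosterior(GaussianDensity(post_g.mean, post_g.cov, names), ev, 1, True)
            (q, F), = update_subjects([prior], [post], group)
            # direct re-inversion: replace the A-block prior with the empirical prior
            mean2 = prior.mean.copy()
            cov2 = np.array(prior.cov, copy=True)
            idx = post.posterior.index_of(block)
            mean2[idx] = group.mean
            cov2[np.ix_(idx, idx)] = group.cov
            prior2 = GaussianDensity(mean2, cov2, names)
            direct, ev2 = linear_gaussian_evidence(X, y, prior2, noise)
            assert np.allclose(q.mean[idx], direct.mean[idx], atol=1e-6)
            assert F == pytest.approx(ev2, abs=1e-6)
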