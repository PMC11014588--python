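"""Hierarchical (group random-effects) model tests: structural
normalization, the prior-variance transform, stacking, and the conjugate
group inversion against the closed-form oracle."""

import numpy as np
import pytest

from structec.errors import (
    DegenerateConnectomeError,
    InsufficientReplicationError,
    InvalidParameterError,
    InvalidTransformError,
    MisalignedSubjectsError,
)
from structec.gaussian import GaussianDensity
from structec.invert import DCMPosterior, a_block_names, dcm_parameter_names, linear_gaussian_evidence
from structec.peb import (
    GroupModel,
    PriorVarianceTransform,
    StructuralConnectivity,
    UNINFORMED,
    build_prior_covariance,
    invert_group,
    normalize_structural,
    stack_subject_means,
    vec_index,
)


def make_posterior(n: int, a_matrix: np.ndarray, extra: float = 0.0) -> DCMPosterior:
    """Toy subject posterior whose A-block mean equals ``a_matrix``."""
    names = dcm_parameter_names(n)
    mean = np.full(len(names), extra)
    mean[: n * n] = np.asarray(a_matrix).flatten(order="F")
    cov = np.eye(len(names)) * 0.01
    return DCMPosterior(GaussianDensity(mean, cov, tuple(names)), free_energy=0.0, iterations=1, converged=True)


class TestStructuralConnectivity:
    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidParameterError):
            StructuralConnectivity(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_all_zero_offdiagonal_rejected(self):
        with pytest.raises(DegenerateConnectomeError):
            StructuralConnectivity(np.diag([1.0, 2.0]))

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            StructuralConnectivity(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNormalizeStructural:
    def test_single_edge(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 5.0
        ct = normalize_structural(StructuralConnectivity(C))
        assert ct[0, 1] == 1.0 and ct[1, 0] == 1.0
        assert np.sum(ct) == 2.0

    def test_diagonal_ignored(self):
        C = np.array([[9.0, 2.0], [2.0, 7.0]])
        ct = normalize_structural(StructuralConnectivity(C))
        assert np.all(np.diag(ct) == 0.0)
        assert ct[0, 1] == 1.0

    def test_matches_bruteforce_division(self, rng):
        w = rng.uniform(0, 2, (5, 5))
        C = (w + w.T) / 2
        np.fill_diagonal(C, 0.0)
        ct = normalize_structural(StructuralConnectivity(C))
        brute = C / np.max(C)
        assert np.allclose(ct, brute)
        assert ct.max() == 1.0 and ct.min() >= 0.0


class TestPriorVarianceTransform:
    def test_uninformed_values(self):
        """The uninformed regime assigns variance 1/2 to every
        inter-regional connection and 1/64 to every self connection."""
        ct = np.zeros((3, 3))
        d = build_prior_covariance(ct, UNINFORMED)
        v = np.diag(d.cov)
        for i in range(3):
            for j in range(3):
                expect = 1.0 / 64.0 if i == j else 0.5
                assert v[vec_index(i, j, 3)] == pytest.approx(expect)

    def test_strongest_edge_gets_alpha_plus_beta(self):
        ct = np.zeros((2, 2))
        ct[0, 1] = ct[1, 0] = 1.0
        t = PriorVarianceTransform(0.1, 0.3, 1 / 64)
        d = build_prior_covariance(ct, t)
        assert np.diag(d.cov)[vec_index(0, 1, 2)] == pytest.approx(0.4)

    def test_matches_bruteforce(self, rng):
        w = rng.uniform(0, 1, (4, 4))
        ct = (w + w.T) / 2
        np.fill_diagonal(ct, 0.0)
        ct /= ct.max()
        t = PriorVarianceTransform(0.05, 0.2, 1 / 32)
        d = build_prior_covariance(ct, t)
        for i in range(4):
            for j in range(4):
                expect = 1 / 32 if i == j else 0.2 * ct[i, j] + 0.05
                assert np.diag(d.cov)[vec_index(i, j, 4)] == pytest.approx(expect)

    def test_symmetric_pairs_get_equal_variance(self, rng):
        w = rng.uniform(0, 1, (5, 5))
        ct = (w + w.T) / 2
        np.fill_diagonal(ct, 0.0)
        ct /= ct.max()
        d = build_prior_covariance(ct, PriorVarianceTransform(0.1, 0.3))
        v = np.diag(d.cov)
        for i in range(5):
            for j in range(i + 1, 5):
                assert v[vec_index(i, j, 5)] == v[vec_index(j, i, 5)]

    def test_monotone_in_structure_when_beta_positive(self):
        ct = np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 0.6], [1.0, 0.6, 0.0]])
        d = build_prior_covariance(ct, PriorVarianceTransform(0.1, 0.4))
        v = np.diag(d.cov)
        assert v[vec_index(0, 2, 3)] > v[vec_index(1, 2, 3)] > v[vec_index(0, 1, 3)]

    @pytest.mark.parametrize("bad", [(-0.1, 0.2, 1 / 64), (0.0, 0.0, 1 / 64), (0.1, 0.1, 0.0)])
    def test_invalid_transform_rejected(self, bad):
        with pytest.raises(InvalidTransformError):
            PriorVarianceTransform(*bad)

    def test_zero_variance_permitted_at_absent_edges(self):
        ct = np.zeros((2, 2))
        ct[0, 1] = ct[1, 0] = 1.0
        d = build_prior_covariance(ct, PriorVarianceTransform(0.0, 0.5))
        # zero variance means the connection is clamped to the prior mean
        assert np.diag(d.cov)[vec_index(0, 1, 2)] == pytest.approx(0.5)


class TestStacking:
    def test_single_subject_identity(self, rng):
        a = rng.standard_normal((2, 2))
        m = stack_subject_means([make_posterior(2, a)])
        assert np.array_equal(m.a1, a.flatten(order="F"))

    def test_permutation_equivariance(self, rng):
        mats = [rng.standard_normal((2, 2)) for _ in range(3)]
        posts = [make_posterior(2, a) for a in mats]
        m1 = stack_subject_means(posts)
        m2 = stack_subject_means(posts[::-1])
        assert np.array_equal(m1.subject_blocks()[::-1], m2.subject_blocks())

    def test_hand_stacked_vector(self):
        mats = [np.array([[float(10 * s + 1), float(10 * s + 3)], [float(10 * s + 2), float(10 * s + 4)]]) for s in range(3)]
        m = stack_subject_means([make_posterior(2, a) for a in mats])
        expect = []
        for s in range(3):
            expect += [10 * s + 1, 10 * s + 2, 10 * s + 3, 10 * s + 4]
        assert np.array_equal(m.a1, np.array(expect, dtype=float))

    def test_misaligned_subjects_rejected(self, rng):
        p2 = make_posterior(2, rng.standard_normal((2, 2)))
        p3 = make_posterior(3, rng.standard_normal((3, 3)))
        with pytest.raises(MisalignedSubjectsError):
            stack_subject_means([p2, p3])


class TestInvertGroup:
    def test_requires_two_subjects(self, rng):
        m = stack_subject_means([make_posterior(2, rng.standard_normal((2, 2)))])
        with pytest.raises(InsufficientReplicationError):
            invert_group(m)

    def test_flat_prior_limit_is_sample_mean(self, rng):
        """With the RFX precision clamped and a nearly flat third-level
        prior, the posterior mean is the across-subject average."""
        mats = [rng.standard_normal((2, 2)) for _ in range(6)]
        m = stack_subject_means([make_posterior(2, a) for a in mats])
        flat = GaussianDensity(np.zeros(4), np.eye(4) * 1e8, m.third_prior.names)
        m2 = GroupModel(m.a1, m.subject_covs, 2, flat)
        res = invert_group(m2, fix_gamma=0.0)
        assert np.allclose(res.posterior.mean, np.mean([a.flatten(order="F") for a in mats], axis=0), atol=1e-6)

    def test_matches_conjugate_oracle(self, rng):
        """Fixed-hyperparameter group inversion equals the closed-form
        linear-Gaussian posterior and evidence."""
        S, n = 4, 2
        mats = [0.3 * rng.standard_normal((n, n)) for _ in range(S)]
        m = stack_subject_means([make_posterior(n, a) for a in mats])
        gamma = 0.7
        res = invert_group(m, fix_gamma=gamma)
        X = np.tile(np.eye(n * n), (S, 1))
        noise_cov = np.kron(np.eye(S), np.diag(np.exp(-gamma) * m.rfx_base_var))
        post, log_ev = linear_gaussian_evidence(X, m.a1, m.third_prior, noise_cov)
        assert np.allclose(res.posterior.mean, post.mean, atol=1e-6)
        assert np.allclose(np.diag(res.posterior.cov), np.diag(post.cov), atol=1e-8)
        assert res.free_energy == pytest.approx(log_ev, abs=1e-6)

    def test_posterior_precision_grows_linearly_with_subjects(self, rng):
        """Adding subjects adds precision: posterior precision of A2 is
        affine in S with slope equal to the per-subject precision."""
        n = 2
        base = rng.standard_normal((n, n))
        gamma = 0.0
        precisions = {}
        for S in (2, 4, 8, 16):
            mats = [base + 0.05 * rng.standard_normal((n, n)) for _ in range(S)]
            m = stack_subject_means([make_posterior(n, a) for a in mats])
            res = invert_group(m, fix_gamma=gamma)
            k = vec_index(1, 0, n)  # an off-diagonal coordinate
            precisions[S] = 1.0 / res.posterior.cov[k, k]
        slopes = [(precisions[2 * s] - precisions[s]) / s for s in (2, 4, 8)]
        per_subject = np.exp(gamma) / m.rfx_base_var[vec_index(1, 0, n)]
        assert np.allclose(slopes, per_subject, rtol=1e-6)

    def test_gamma_recovers_rfx_scale(self, rng):
        """The optimized hyperparameter tracks the true between-subject
        variance on the natural log scale."""
        n, S = 3, 40
        truth = 0.4 * rng.standard_normal((n, n))
        rfx_var = 0.01
        mats = [truth + np.sqrt(rfx_var) * rng.standard_normal((n, n)) for _ in range(S)]
        m = stack_subject_means([make_posterior(n, a) for a in mats])
        res = invert_group(m)
        est_var = np.exp(-res.gamma_mean) * m.rfx_base_var[vec_index(1, 0, n)]
        # order-of-magnitude recovery (the single gamma also has to serve
        # the self-connection coordinates, whose base variance differs)
        assert 0.2 * rfx_var < est_var < 5.0 * rfx_var

    def test_deterministic(self, rng):
        mats = [rng.standard_normal((2, 2)) for _ in range(4)]
        posts = [make_posterior(2, a) for a in mats]
        r1 = invert_group(stack_subject_means(posts))
        r2 = invert_group(stack_subject_means(posts))
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.posterior.mean, r2.posterior.mean)
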