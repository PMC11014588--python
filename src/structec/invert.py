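"""Variational Laplace inversion of a single subject's spectral DCM.

The approximate posterior ``q(theta) = N(mu, Sigma)`` over the full
parameter vector (effective connectivity, hemodynamics, noise spectra)
is optimized by Gauss-Newton ascent on the variational free energy

.. math::

    F = E_q[\\ln p(y \\mid \\theta)] - KL(q \\Vert p),

with Levenberg-Marquardt damping and a local linearization of the
forward model at the posterior mean.  The data vector ``y`` stacks the
non-redundant real and imaginary parts of the observed cross-spectral
density (upper triangle, diagonal real only) across all grid
frequencies; observation noise is IID Gaussian on that vector with a
single log-precision hyperparameter per subject.

Parameter vector layout for an ``n``-region network (names exposed on
every density):

* ``A[i,j]`` (n^2, column-major) — off-diagonal entries are coupling
  rates in Hz; diagonal entries are log-scaling factors with
  ``A_ii = -1/2 * exp(a_ii)`` Hz, guaranteeing negative self-connections.
* ``decay[r]``, ``transit[r]`` — hemodynamic log-scaling factors.
* ``v_amp[r]``, ``v_exp``, ``e_amp[r]``, ``e_exp`` — power-law noise
  log-amplitudes (per region) and shared log-exponents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePosteriorError, DegenerateModelError, InvalidParameterError
from .forward import (
    BALLOON,
    BalloonConstants,
    CrossSpectra,
    EffectiveConnectivity,
    FrequencyGrid,
    HemodynamicParams,
    NoiseSpectraParams,
    predicted_csd,
    predicted_csd_many,
)
from .gaussian import GaussianDensity, gaussian_kl, logdet_psd, robust_precision

logger = logging.getLogger(__name__)

__all__ = [
    "DCMPriors",
    "DCMPosterior",
    "InversionSettings",
    "dcm_parameter_names",
    "a_block_names",
    "default_dcm_priors",
    "make_predictor",
    "unpack_parameters",
    "stack_csd",
    "calibrate_csd_scale",
    "free_energy",
    "variational_laplace",
    "invert_dcm",
    "linear_gaussian_evidence",
]

# Subject-level prior variances (ecosystem defaults: 1/64 on
# connectivity, 1/16 on hemodynamic and noise log-parameters).
VAR_A_OFFDIAG = 1.0 / 64.0
VAR_A_DIAG = 1.0 / 64.0
VAR_A_WARMSTART = 1.0 / 64.0
VAR_HEMO = 1.0 / 16.0
VAR_NOISE = 1.0 / 16.0
SELF_RATE = -0.5  # Hz at a_ii = 0


def a_block_names(n: int) -> list[str]:
    """Column-major names of the vectorized A-block (diagonal included)."""
    return [f"A[{i},{j}]" for j in range(n) for i in range(n)]


def dcm_parameter_names(n: int) -> list[str]:
    names = a_block_names(n)
    names += [f"decay[{r}]" for r in range(n)]
    names += [f"transit[{r}]" for r in range(n)]
    names += [f"v_amp[{r}]" for r in range(n)]
    names += ["v_exp"]
    names += [f"e_amp[{r}]" for r in range(n)]
    names += ["e_exp"]
    return names


def unpack_parameters(theta: np.ndarray, n: int, constants: BalloonConstants = BALLOON):
    """Split a parameter vector into model components.

    Returns ``(EffectiveConnectivity, HemodynamicParams, NoiseSpectraParams)``.
    """
    theta = np.asarray(theta, dtype=float)
    n2 = n * n
    a = theta[:n2].reshape(n, n, order="F").copy()
    diag_log = np.diag(a).copy()
    np.fill_diagonal(a, SELF_RATE * np.exp(diag_log))
    hem = HemodynamicParams(theta[n2 : n2 + n], theta[n2 + n : n2 + 2 * n], constants)
    k = n2 + 2 * n
    noise = NoiseSpectraParams(theta[k : k + n], float(theta[k + n]), theta[k + n + 1 : k + 2 * n + 1], float(theta[k + 2 * n + 1]))
    return EffectiveConnectivity(a), hem, noise


@dataclass(frozen=True)
class DCMPriors:
    """Gaussian prior over the full DCM parameter vector plus the
    observation-noise log-precision hyperprior."""

    prior: GaussianDensity
    noise_hyper_mean: float = 6.0
    noise_hyper_var: float = 1.0 / 16.0

    @property
    def dim(self) -> int:
        return self.prior.dim


def default_dcm_priors(n: int, noise_hyper_mean: float = 6.0, noise_hyper_var: float = 1.0 / 16.0) -> DCMPriors:
    names = dcm_parameter_names(n)
    var = np.empty(len(names))
    for k, nm in enumerate(names):
        if nm.startswith("A["):
            i, j = map(int, nm[2:-1].split(","))
            var[k] = VAR_A_DIAG if i == j else VAR_A_OFFDIAG
        elif nm.startswith(("decay", "transit")):
            var[k] = VAR_HEMO
        else:
            var[k] = VAR_NOISE
    prior = GaussianDensity(np.zeros(len(names)), np.diag(var), tuple(names))
    return DCMPriors(prior, noise_hyper_mean, noise_hyper_var)


def _stack_matrices(m: np.ndarray) -> np.ndarray:
    """Stack Hermitian matrices (..., F, n, n) into real feature vectors
    (..., N): upper-triangle real parts (diagonal included) then strict
    upper-triangle imaginary parts, per frequency."""
    n = m.shape[-1]
    iu = np.triu_indices(n)
    ius = np.triu_indices(n, k=1)
    re = m[..., iu[0], iu[1]].real  # (..., F, n(n+1)/2)
    im = m[..., ius[0], ius[1]].imag  # (..., F, n(n-1)/2)
    out = np.concatenate([re, im], axis=-1)
    return out.reshape(out.shape[:-2] + (-1,))


def stack_csd(csd: CrossSpectra) -> np.ndarray:
    """Non-redundant real feature vector of a Hermitian CSD sequence:
    per frequency, the real parts of the upper triangle (diagonal
    included) followed by the imaginary parts of the strict upper
    triangle."""
    return _stack_matrices(csd.matrices)


def make_predictor(n: int, grid: FrequencyGrid, constants: BalloonConstants = BALLOON):
    """Forward-model handle mapping a parameter vector to the stacked CSD
    feature vector (same stacking as :func:`stack_csd`).

    The returned callable also carries ``predict_many`` for batched
    evaluation of a (P, d) matrix of parameter vectors, used by the
    finite-difference Jacobian.
    """
    n2 = n * n

    def predict(theta: np.ndarray) -> np.ndarray:
        A, hem, noise = unpack_parameters(theta, n, constants)
        return stack_csd(predicted_csd(A, hem, noise, grid))

    def predict_many(thetas: np.ndarray) -> np.ndarray:
        thetas = np.asarray(thetas, dtype=float)
        P = thetas.shape[0]
        a = thetas[:, :n2].reshape(P, n, n).transpose(0, 2, 1).copy()  # column-major per sample
        di = np.arange(n)
        a[:, di, di] = SELF_RATE * np.exp(a[:, di, di])
        k = n2 + 2 * n
        G = predicted_csd_many(
            a,
            thetas[:, n2 : n2 + n],
            thetas[:, n2 + n : n2 + 2 * n],
            thetas[:, k : k + n],
            thetas[:, k + n],
            thetas[:, k + n + 1 : k + 2 * n + 1],
            thetas[:, k + 2 * n + 1],
            grid,
            constants,
        )
        return _stack_matrices(G)

    predict.n_regions = n
    predict.grid = grid
    predict.n_outputs = len(grid) * n * n
    predict.predict_many = predict_many
    return predict


def calibrate_csd_scale(data: CrossSpectra, priors: DCMPriors, constants: BalloonConstants = BALLOON) -> tuple[CrossSpectra, float]:
    """Rescale observed cross-spectra onto the generative model's scale.

    The predicted CSD at the prior mean fixes the model's natural power
    scale; the data are multiplied by a single positive factor so that
    the mean diagonal power matches it.  The residual mismatch is
    absorbed by the noise log-amplitude parameters.  Returns the scaled
    copy and the factor applied.
    """
    n = data.n
    A, hem, noise = unpack_parameters(priors.prior.mean, n, constants)
    ref = predicted_csd(A, hem, noise, data.grid)
    num = float(np.mean(np.diagonal(ref.matrices, axis1=1, axis2=2).real))
    den = float(np.mean(np.diagonal(data.matrices, axis1=1, axis2=2).real))
    if den <= 0:
        raise InvalidParameterError("data cross-spectra have non-positive mean diagonal power")
    factor = num / den
    return CrossSpectra(data.grid, data.matrices * factor), factor


def _jacobian(predict, theta: np.ndarray, g0: np.ndarray, step: float) -> np.ndarray:
    """Forward finite-difference Jacobian (n_outputs x dim); uses the
    predictor's batched path when it provides one."""
    d = theta.size
    many = getattr(predict, "predict_many", None)
    if many is not None:
        thetas = np.broadcast_to(theta, (d, d)).copy()
        thetas[np.diag_indices(d)] += step
        return (many(thetas) - g0[None, :]).T / step
    J = np.empty((g0.size, d))
    for k in range(d):
        tp = theta.copy()
        tp[k] += step
        J[:, k] = (predict(tp) - g0) / step
    return J


def free_energy(
    q: GaussianDensity,
    prior: GaussianDensity,
    data: CrossSpectra,
    predictor,
    noise_precision: float,
    fd_step: float = 1e-4,
) -> float:
    """Variational free energy of ``q`` under a Gaussian likelihood.

    ``E_q[ln p(y|theta)]`` is evaluated by linearizing the forward model
    at the posterior mean: ``ln N(y; g(mu), I/precision) - 1/2 tr(Sigma_q
    J' Pi_e J)``; the KL term uses the exact Gaussian formula.
    """
    if q.dim != prior.dim:
        raise InvalidParameterError("q/prior dimension mismatch")
    if noise_precision <= 0:
        raise InvalidParameterError("noise precision must be positive")
    scale = max(1.0, float(np.max(np.abs(q.cov))))
    if np.min(np.linalg.eigvalsh(0.5 * (q.cov + q.cov.T))) < 1e-14 * scale:
        raise DegeneratePosteriorError("approximate posterior covariance is singular")
    y = stack_csd(data)
    g0 = predictor(q.mean)
    J = _jacobian(predictor, q.mean, g0, fd_step)
    r = y - g0
    N = y.size
    ell = -0.5 * N * np.log(2 * np.pi) + 0.5 * N * np.log(noise_precision) - 0.5 * noise_precision * (r @ r)
    ell -= 0.5 * noise_precision * float(np.sum((J @ q.cov) * J))
    return float(ell - gaussian_kl(q, prior))


@dataclass(frozen=True)
class InversionSettings:
    """Gauss-Newton / Levenberg-Marquardt settings for subject inversion."""

    max_iter: int = 128
    tol: float = 1e-4  # |dF| threshold
    tol_consecutive: int = 3
    fd_step: float = 1e-4
    init_damping: float = 1.0
    damping_increase: float = 4.0
    damping_decrease: float = 0.5
    max_damping_tries: int = 8
    fix_noise_log_precision: float | None = None
    # prior-continuation warm start: first optimize under a tighter
    # off-diagonal connectivity prior (stabilizing the ascent), then
    # re-optimize under the requested prior from that iterate
    warm_start_a_variance: float | None = VAR_A_WARMSTART


@dataclass(frozen=True)
class DCMPosterior:
    """Result of a subject-level inversion."""

    posterior: GaussianDensity
    free_energy: float
    iterations: int
    converged: bool
    noise_log_precision: float = 0.0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.free_energy):
            raise InvalidParameterError("free energy must be finite")


def _free_energy_terms(y, g0, J, mu, prior_mean, Pi0, ld_prior, lam, lam_mean, lam_var, lam_fixed):
    """Free energy given the local linearization (J at mu)."""
    N = y.size
    r = y - g0
    tau = np.exp(lam)
    H = tau * (J.T @ J) + Pi0
    sign, ld_H = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, None, None
    Sigma = np.linalg.inv(H)
    e = mu - prior_mean
    ell = -0.5 * N * np.log(2 * np.pi) + 0.5 * N * lam - 0.5 * tau * (r @ r)
    ell -= 0.5 * tau * float(np.sum((J @ Sigma) * J))
    # KL(q || prior) with Sigma the curvature-matched posterior covariance
    kl = 0.5 * (float(np.trace(Pi0 @ Sigma)) + float(e @ Pi0 @ e) - mu.size + ld_prior + ld_H)
    F = ell - kl
    if not lam_fixed:
        F += -0.5 * (lam - lam_mean) ** 2 / lam_var
    return float(F), Sigma, H


def _update_lambda(y, g0, J, Pi0, lam, lam_mean, lam_var, n_newton: int = 8):
    """Scalar Newton ascent on F with respect to the noise log-precision."""
    N = y.size
    r = y - g0
    rr = float(r @ r)
    JJ = J.T @ J
    for _ in range(n_newton):
        tau = np.exp(lam)
        Sigma = np.linalg.inv(tau * JJ + Pi0)
        t = rr + float(np.sum(Sigma * JJ))
        grad = 0.5 * N - 0.5 * tau * t - (lam - lam_mean) / lam_var
        hess = -0.5 * tau * t - 1.0 / lam_var
        step = grad / hess
        lam = float(np.clip(lam - step, lam - 2.0, lam + 2.0))
        if abs(step) < 1e-6:
            break
    return lam


def variational_laplace(
    y: np.ndarray,
    predict,
    prior: GaussianDensity,
    settings: InversionSettings = InversionSettings(),
    noise_hyper_mean: float = 6.0,
    noise_hyper_var: float = 1.0 / 16.0,
    trace: list | None = None,
    init_mean: np.ndarray | None = None,
):
    """Gauss-Newton / Levenberg-Marquardt ascent of the free energy.

    Generic engine behind :func:`invert_dcm`: ``predict`` maps a
    parameter vector to the model prediction of ``y``.  Accepted steps
    never decrease the free energy (candidates are scored with their own
    local linearization before acceptance); ``trace``, when given,
    collects the free energy after every accepted step.  Returns
    ``(q, F, iterations, converged, lam)``.
    """
    Pi0 = robust_precision(prior.cov)
    ld_prior = logdet_psd(prior.cov)
    mu = prior.mean.copy() if init_mean is None else np.asarray(init_mean, dtype=float).copy()
    lam_fixed = settings.fix_noise_log_precision is not None
    lam = settings.fix_noise_log_precision if lam_fixed else noise_hyper_mean

    g0 = predict(mu)
    J = _jacobian(predict, mu, g0, settings.fd_step)
    if not lam_fixed:
        lam = _update_lambda(y, g0, J, Pi0, lam, noise_hyper_mean, noise_hyper_var)
    F, Sigma, H = _free_energy_terms(y, g0, J, mu, prior.mean, Pi0, ld_prior, lam, noise_hyper_mean, noise_hyper_var, lam_fixed)
    if Sigma is None:
        raise DegeneratePosteriorError("initial curvature matrix is not positive definite")
    if trace is not None:
        trace.append(F)

    damping = settings.init_damping
    small_steps = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, settings.max_iter + 1):
        tau = np.exp(lam)
        grad = tau * (J.T @ (y - g0)) - Pi0 @ (mu - prior.mean)
        accepted = False
        for _try in range(settings.max_damping_tries):
            Hd = H + damping * np.diag(np.diag(H))
            try:
                dmu = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                damping *= settings.damping_increase
                continue
            mu_c = mu + dmu
            g0_c = predict(mu_c)
            if not np.all(np.isfinite(g0_c)):
                damping *= settings.damping_increase
                continue
            J_c = _jacobian(predict, mu_c, g0_c, settings.fd_step)
            lam_c = lam if lam_fixed else _update_lambda(y, g0_c, J_c, Pi0, lam, noise_hyper_mean, noise_hyper_var)
            F_c, Sigma_c, H_c = _free_energy_terms(y, g0_c, J_c, mu_c, prior.mean, Pi0, ld_prior, lam_c, noise_hyper_mean, noise_hyper_var, lam_fixed)
            if Sigma_c is not None and F_c >= F:
                dF = F_c - F
                mu, g0, J, lam, F, Sigma, H = mu_c, g0_c, J_c, lam_c, F_c, Sigma_c, H_c
                damping = max(damping * settings.damping_decrease, 1e-8)
                accepted = True
                if trace is not None:
                    trace.append(F)
                small_steps = small_steps + 1 if dF < settings.tol else 0
                break
            damping *= settings.damping_increase
        if not accepted:
            small_steps += 1
        if small_steps >= settings.tol_consecutive:
            converged = True
            break

    q = GaussianDensity(mu, 0.5 * (Sigma + Sigma.T), prior.names)
    return q, float(F), n_iter, converged, float(lam)


def invert_dcm(
    data: CrossSpectra,
    priors: DCMPriors,
    settings: InversionSettings = InversionSettings(),
    constants: BalloonConstants = BALLOON,
    grid: FrequencyGrid | None = None,
) -> DCMPosterior:
    """Invert one subject's spectral DCM by Gauss-Newton free-energy ascent.

    Deterministic given identical inputs and settings.  If the maximum
    iteration count is reached without the free-energy change staying
    below ``tol`` for ``tol_consecutive`` iterations, the best iterate is
    returned with ``converged=False`` and a warning is logged.
    """
    grid = grid or data.grid
    n = data.n
    prior = priors.prior
    if prior.dim != len(dcm_parameter_names(n)):
        raise InvalidParameterError("prior dimension does not match the DCM parameterization")
    predict = make_predictor(n, grid, constants)
    y = stack_csd(data)
    # work in unit-RMS feature units so the noise log-precision hyperprior
    # refers to a fixed scale regardless of the data's power units
    c = float(np.sqrt(np.mean(y**2)))
    if c <= 0 or not np.isfinite(c):
        raise InvalidParameterError("data features have no power")
    y_u = y / c

    def predict_u(theta: np.ndarray) -> np.ndarray:
        return predict(theta) / c

    predict_u.predict_many = lambda thetas: predict.predict_many(thetas) / c

    init = None
    wv = settings.warm_start_a_variance
    if wv is not None:
        a_off = [k for k, nm in enumerate(prior.names) if nm.startswith("A[") and nm[2:-1].split(",")[0] != nm[2:-1].split(",")[1]]
        if a_off and abs(prior.cov[a_off[0], a_off[0]] - wv) > 1e-12:
            cov_w = np.array(prior.cov, copy=True)
            cov_w[a_off, a_off] = wv
            prior_w = GaussianDensity(prior.mean, cov_w, prior.names)
            q_w, _, _, _, _ = variational_laplace(
                y_u, predict_u, prior_w, settings, priors.noise_hyper_mean, priors.noise_hyper_var
            )
            init = q_w.mean

    q, F, n_iter, converged, lam = variational_laplace(
        y_u, predict_u, prior, settings, priors.noise_hyper_mean, priors.noise_hyper_var, init_mean=init
    )
    if not converged:
        logger.warning("invert_dcm: no convergence within %d iterations (|dF| tol %g)", settings.max_iter, settings.tol)
    return DCMPosterior(q, F, n_iter, converged, lam)


def linear_gaussian_evidence(
    design: np.ndarray,
    data: np.ndarray,
    prior: GaussianDensity,
    noise_cov: np.ndarray,
) -> tuple[GaussianDensity, float]:
    """Exact conjugate posterior and log evidence of y = X theta + e.

    ``e ~ N(0, noise_cov)``, ``theta ~ prior``.  Serves as the
    independent closed-form oracle for free-energy and model-reduction
    computations throughout the package.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.atleast_1d(np.asarray(data, dtype=float))
    Se = np.asarray(noise_cov, dtype=float)
    if Se.ndim == 1:
        Se = np.diag(Se)
    if X.shape[0] != y.size or X.shape[1] != prior.dim or Se.shape != (y.size, y.size):
        raise InvalidParameterError("non-conformable linear-Gaussian model")
    marginal_cov = Se + X @ prior.cov @ X.T
    sign, ld = np.linalg.slogdet(marginal_cov)
    if sign <= 0:
        raise DegenerateModelError("singular marginal covariance")
    r = y - X @ prior.mean
    log_evidence = float(-0.5 * (y.size * np.log(2 * np.pi) + ld + r @ np.linalg.solve(marginal_cov, r)))
    # Gaussian conditioning in covariance form: exact even for singular
    # prior covariances (zero-variance coordinates stay at the prior mean)
    gain = prior.cov @ X.T @ np.linalg.inv(marginal_cov)
    mu = prior.mean + gain @ r
    Sigma = prior.cov - gain @ X @ prior.cov
    return GaussianDensity(mu, 0.5 * (Sigma + Sigma.T), prior.names), log_evidence
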