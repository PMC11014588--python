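"""Analytic Bayesian model reduction (BMR) and Bayesian model averaging.

Given a model already inverted under a "full" prior, BMR computes the
posterior and free energy that *would* have been obtained under any
alternative ("reduced") prior with the same likelihood, in closed form:

.. math::

    \\tilde\\Pi_q = \\Pi_q + \\tilde\\Pi_0 - \\Pi_0, \\qquad
    \\tilde\\mu_q = \\tilde\\Sigma_q (\\Pi_q \\mu_q + \\tilde\\Pi_0
    \\tilde\\mu_0 - \\Pi_0 \\mu_0),

with the free-energy change given by the log-determinant and quadratic
terms of the Gaussian algebra.  The same routine serves two levels of
the hierarchy: scoring structure-based third-level priors against the
uninformed group model, and propagating the group posterior downward as
an empirical prior on each subject's effective connectivity.

The grid search enumerates linear prior-variance transforms
``sigma^2 = beta * c~ + alpha`` over a triangular (alpha, beta) region,
scores each by BMR, and averages the hyperparameters under softmax
(free-energy) weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyGridError, ImproperReductionError, InvalidParameterError, MisalignedParametersError
from .gaussian import GaussianDensity, robust_precision
from .invert import DCMPosterior
from .peb import PEBResult, PriorVarianceTransform, build_prior_covariance

__all__ = [
    "ReducedModelResult",
    "GridSpec",
    "BMAResult",
    "STRONG_EVIDENCE_THRESHOLD",
    "bmr_gaussian",
    "enumerate_regimes",
    "score_grid",
    "bma_average",
    "log_bayes_factor",
    "update_subjects",
]

#: Conventional "strong evidence" threshold on a log-Bayes factor
#: (about e^3, i.e. twenty-fold).  Documented, never enforced.
STRONG_EVIDENCE_THRESHOLD = 3.0

# Variance floor standing in for "exactly clamped" coordinates: a reduced
# prior variance of zero is replaced by this floor so all precisions stay
# finite while the posterior is driven to the prior mean.
_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class ReducedModelResult:
    """Posterior and free-energy change of a reduced model."""

    reduced_posterior: GaussianDensity
    delta_free_energy: float
    reduced_free_energy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_free_energy) and np.isfinite(self.reduced_free_energy)):
            raise InvalidParameterError("non-finite free energy in reduction result")


def _floored_cov(cov: np.ndarray) -> np.ndarray:
    """Raise exactly-zero diagonal variances to the clamping floor."""
    cov = np.array(cov, dtype=float, copy=True)
    d = np.diag(cov)
    zero = d < _VAR_FLOOR
    if np.any(zero):
        idx = np.where(zero)[0]
        cov[idx, idx] = _VAR_FLOOR
    return cov


def bmr_gaussian(
    full_prior: GaussianDensity,
    full_posterior: GaussianDensity,
    reduced_prior: GaussianDensity,
    full_free_energy: float = 0.0,
) -> ReducedModelResult:
    """Analytic model reduction for Gaussian prior/posterior pairs.

    Applying the identity reduction (``reduced_prior == full_prior``)
    returns the full posterior with a free-energy change of exactly zero.
    A reduction whose implied posterior precision is not positive
    semidefinite raises :class:`ImproperReductionError` reporting the
    offending eigenvalue.
    """
    d = full_prior.dim
    if full_posterior.dim != d or reduced_prior.dim != d:
        raise MisalignedParametersError("densities must share dimension")
    if full_prior.names and reduced_prior.names and full_prior.names != reduced_prior.names:
        raise MisalignedParametersError("full and reduced priors must share parameter naming")
    if np.array_equal(reduced_prior.mean, full_prior.mean) and np.array_equal(reduced_prior.cov, full_prior.cov):
        # identity reduction: the posterior is untouched and dF is exactly 0
        return ReducedModelResult(full_posterior, 0.0, float(full_free_energy))

    Pi0 = robust_precision(_floored_cov(full_prior.cov))
    Piq = robust_precision(_floored_cov(full_posterior.cov))
    Pir = robust_precision(_floored_cov(reduced_prior.cov))

    Pir_q = Piq + Pir - Pi0
    Pir_q = 0.5 * (Pir_q + Pir_q.T)
    w = np.linalg.eigvalsh(Pir_q)
    if w[0] <= 0:
        raise ImproperReductionError(f"reduced posterior precision has eigenvalue {w[0]:g} <= 0")
    Sr = np.linalg.inv(Pir_q)
    Sr = 0.5 * (Sr + Sr.T)
    h = Piq @ full_posterior.mean + Pir @ reduced_prior.mean - Pi0 @ full_prior.mean
    mur = Sr @ h

    def _ld(M: np.ndarray) -> float:
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise ImproperReductionError("non-positive determinant in reduction")
        return float(ld)

    dF = 0.5 * (_ld(Pir) + _ld(Piq) - _ld(Pi0) - _ld(Pir_q))
    dF -= 0.5 * (
        full_posterior.mean @ Piq @ full_posterior.mean
        + reduced_prior.mean @ Pir @ reduced_prior.mean
        - full_prior.mean @ Pi0 @ full_prior.mean
        - mur @ Pir_q @ mur
    )
    post = GaussianDensity(mur, Sr, full_posterior.names)
    return ReducedModelResult(post, float(dF), float(full_free_energy + dF))


@dataclass(frozen=True)
class GridSpec:
    """Triangular (alpha, beta) sampling grid for the prior-variance transform.

    alpha is sampled at ``alpha_points`` equidistant values over
    ``alpha_range``; per alpha, beta at ``beta_points`` equidistant values
    over [0, 1/2 - alpha].  Combinations violating ``alpha >= 0`` or
    ``alpha + beta >= 1e-5`` are filtered out after construction.
    """

    alpha_points: int = 30
    alpha_range: tuple[float, float] = (-0.5, 0.5)
    beta_points: int = 30
    delta: float = 1.0 / 64.0

    def __post_init__(self) -> None:
        if self.alpha_points < 1 or self.beta_points < 1:
            raise InvalidParameterError("grid point counts must be positive")
        if self.alpha_range[1] < self.alpha_range[0]:
            raise InvalidParameterError("invalid alpha range")


def enumerate_regimes(spec: GridSpec) -> list[PriorVarianceTransform]:
    """Deterministic alpha-major enumeration of admissible transforms."""
    if spec.alpha_points == 1:
        alphas = np.array([spec.alpha_range[0]])
    else:
        alphas = np.linspace(spec.alpha_range[0], spec.alpha_range[1], spec.alpha_points)
    regimes: list[PriorVarianceTransform] = []
    for a in alphas:
        hi = 0.5 - a
        if spec.beta_points == 1 or hi <= 0:
            betas = np.array([max(hi, 0.0)])
        else:
            betas = np.linspace(0.0, hi, spec.beta_points)
        for b in betas:
            if a < 0 or a + b < PriorVarianceTransform.MIN_TOTAL:
                continue
            regimes.append(PriorVarianceTransform(float(a), float(b), spec.delta))
    if not regimes:
        raise EmptyGridError("no admissible (alpha, beta) combinations")
    return regimes


def score_grid(
    group_full: PEBResult,
    full_prior: GaussianDensity,
    c_tilde: np.ndarray,
    regimes: list[PriorVarianceTransform],
) -> np.ndarray:
    """Free-energy change of every structure-based regime, via BMR.

    ``group_full`` must be the group model inverted under the uninformed
    (full) third-level prior; no re-optimization occurs.  Stateless in
    the regime ordering.
    """
    Fk = np.empty(len(regimes))
    for k, t in enumerate(regimes):
        reduced = build_prior_covariance(c_tilde, t)
        try:
            Fk[k] = bmr_gaussian(full_prior, group_full.posterior, reduced).delta_free_energy
        except ImproperReductionError as e:
            raise ImproperReductionError(f"regime {k} (alpha={t.alpha:g}, beta={t.beta:g}): {e}") from e
    return Fk


@dataclass(frozen=True)
class BMAResult:
    """Evidence-weighted average over prior-variance regimes."""

    regimes: tuple[PriorVarianceTransform, ...]
    free_energies: np.ndarray
    weights: np.ndarray
    alpha_bar: float
    beta_bar: float
    envelope_c: np.ndarray  # c~ evaluation points
    envelope_lo: np.ndarray  # weighted 2.5th percentile of sigma^2(c~)
    envelope_hi: np.ndarray  # weighted 97.5th percentile

    @property
    def averaged(self) -> PriorVarianceTransform:
        return PriorVarianceTransform(max(self.alpha_bar, 0.0), self.beta_bar, self.regimes[0].delta)


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cw, v))


def bma_average(Fk: np.ndarray, regimes: list[PriorVarianceTransform], envelope_points: int = 101) -> BMAResult:
    """Softmax-weighted average of regime hyperparameters.

    Weights are computed after subtracting ``max(Fk)`` so that free-energy
    differences of hundreds of nats cannot overflow; the result is
    exactly invariant to adding a constant to all free energies.  The
    95% envelope holds weighted percentiles of ``sigma^2(c~)`` over the
    regimes at equidistant ``c~`` values.
    """
    Fk = np.asarray(Fk, dtype=float)
    if Fk.ndim != 1 or Fk.size != len(regimes) or Fk.size == 0:
        raise InvalidParameterError("free-energy vector does not match regimes")
    if not np.all(np.isfinite(Fk)):
        raise InvalidParameterError("free energies must be finite")
    z = Fk - Fk.max()
    w = np.exp(z)
    total = w.sum()
    assert total >= 1.0  # max-subtraction guarantees at least one unit weight
    w /= total
    alphas = np.array([t.alpha for t in regimes])
    betas = np.array([t.beta for t in regimes])
    a_bar = float(w @ alphas)
    b_bar = float(w @ betas)
    c = np.linspace(0.0, 1.0, envelope_points)
    sig = betas[:, None] * c[None, :] + alphas[:, None]  # (K, P)
    lo = np.array([_weighted_percentile(sig[:, p], w, 0.025) for p in range(c.size)])
    hi = np.array([_weighted_percentile(sig[:, p], w, 0.975) for p in range(c.size)])
    return BMAResult(tuple(regimes), Fk, w, a_bar, b_bar, c, lo, hi)


def log_bayes_factor(F1: float, F2: float) -> float:
    """Difference of log evidences (free energies): ln BF(1,2) = F1 - F2."""
    if not (np.isfinite(F1) and np.isfinite(F2)):
        raise InvalidParameterError("free energies must be finite")
    return float(F1 - F2)


def update_subjects(
    subject_priors: list[GaussianDensity],
    subject_posteriors: list[DCMPosterior],
    group_posterior: GaussianDensity,
) -> list[tuple[GaussianDensity, float]]:
    """Downward empirical-prior update of every subject's A-block.

    The group posterior ``q(A2 | A1)`` replaces the subject's prior on
    the A-block (an empirical prior); BMR yields the updated posterior
    and free energy.  Parameters outside the A-block pass through
    unchanged; the cross-covariance between the updated block and the
    remaining parameters is zeroed, since the reduction is performed on
    the A-block marginal.
    """
    if len(subject_priors) != len(subject_posteriors):
        raise MisalignedParametersError("priors/posteriors count mismatch")
    if not group_posterior.names:
        raise MisalignedParametersError("group posterior must carry parameter names")
    out: list[tuple[GaussianDensity, float]] = []
    for prior, post in zip(subject_priors, subject_posteriors):
        if prior.names != post.posterior.names:
            raise MisalignedParametersError("subject prior/posterior naming mismatch")
        idx = post.posterior.index_of(list(group_posterior.names))
        p_marg = prior.marginal(idx)
        q_marg = post.posterior.marginal(idx)
        red = bmr_gaussian(p_marg, q_marg, group_posterior, post.free_energy)
        mean = post.posterior.mean.copy()
        cov = np.array(post.posterior.cov, copy=True)
        mean[idx] = red.reduced_posterior.mean
        cov[np.ix_(idx, idx)] = red.reduced_posterior.cov
        rest = np.setdiff1d(np.arange(post.posterior.dim), idx)
        cov[np.ix_(idx, rest)] = 0.0
        cov[np.ix_(rest, idx)] = 0.0
        out.append((GaussianDensity(mean, cov, post.posterior.names), red.reduced_free_energy))
    return out
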