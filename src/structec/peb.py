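"""Hierarchical random-effects model over subject-level effective connectivity.

Stacking the vectorized subject posterior means ``A1 = [vec A_1; ...;
vec A_S]`` yields the linear random-effects model

.. math::

    A^{(1)} = (1 \\otimes I) A^{(2)} + \\varepsilon^{(2)}, \\qquad
    A^{(2)} \\sim N(\\mu_3, \\Sigma_3),

where the third-level prior covariance encodes structural connectivity:
off-diagonal connections receive variance ``sigma^2_ij = beta *
c~_ij + alpha`` (a linear function of normalized structural
connectivity) and self-connections receive ``delta``.  The
between-subject covariance is a single scaled precision component
``Sigma_2 = exp(-gamma) * Q`` whose base ``Q`` is the diagonal of the
subject-level prior variances on the A-block; the log-scale
hyperparameter ``gamma`` carries a Gaussian hyperprior and is optimized
by scalar free-energy ascent.  Conditional on ``gamma`` the model is
linear-Gaussian, so ``q(A2 | A1)`` has the conjugate closed form.

Subject posterior means enter the second level as data without their
covariances; those covariances are retained on the :class:`GroupModel`
and re-enter only in the downward Bayesian-model-reduction updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    DegenerateConnectomeError,
    InsufficientReplicationError,
    InvalidParameterError,
    InvalidTransformError,
    MisalignedSubjectsError,
)
from .gaussian import GaussianDensity
from .invert import VAR_A_DIAG, VAR_A_OFFDIAG, DCMPosterior, a_block_names

__all__ = [
    "StructuralConnectivity",
    "PriorVarianceTransform",
    "GroupModel",
    "PEBResult",
    "UNINFORMED",
    "vec_index",
    "normalize_structural",
    "build_prior_covariance",
    "stack_subject_means",
    "invert_group",
]


def vec_index(i: int, j: int, n: int) -> int:
    """Position of matrix entry (i, j) in the column-major vectorization."""
    return j * n + i


@dataclass(frozen=True)
class StructuralConnectivity:
    """Nonnegative symmetric anatomical connection-weight matrix."""

    weights: np.ndarray
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("structural connectivity must be square")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("structural connectivity has non-finite entries")
        if np.any(w < 0):
            raise InvalidParameterError("structural connectivity must be nonnegative")
        if np.max(np.abs(w - w.T)) > 1e-10:
            raise InvalidParameterError("structural connectivity must be symmetric")
        off = w - np.diag(np.diag(w))
        if np.max(off) <= 0:
            raise DegenerateConnectomeError("no positive off-diagonal structural weight")
        labels = tuple(self.region_labels) or tuple(f"R{i}" for i in range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise InvalidParameterError("region_labels length mismatch")
        object.__setattr__(self, "region_labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def normalize_structural(C: StructuralConnectivity) -> np.ndarray:
    """Normalized structural connectivity: zero the diagonal and divide by
    the maximum off-diagonal weight, so entries lie in [0, 1] with the
    strongest edge exactly 1."""
    w = C.weights.copy()
    np.fill_diagonal(w, 0.0)
    m = np.max(w)
    if m <= 0:
        raise DegenerateConnectomeError("all off-diagonal structural weights are zero")
    return w / m


@dataclass(frozen=True)
class PriorVarianceTransform:
    """Linear map from normalized structural connectivity to prior variance.

    ``sigma^2_ij = beta * c~_ij + alpha`` for inter-regional connections;
    intra-regional (self) connections get the fixed variance ``delta``.
    """

    alpha: float
    beta: float
    delta: float = 1.0 / 64.0

    MIN_TOTAL = 1e-5

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.alpha, self.beta, self.delta])):
            raise InvalidTransformError("transform hyperparameters must be finite")
        if self.alpha < 0:
            raise InvalidTransformError(f"alpha must be nonnegative (got {self.alpha})")
        if self.alpha + self.beta < self.MIN_TOTAL:
            raise InvalidTransformError(f"alpha + beta must be >= {self.MIN_TOTAL}")
        if self.delta <= 0:
            raise InvalidTransformError("delta must be positive")

    def variance(self, c_tilde: np.ndarray | float) -> np.ndarray | float:
        return self.beta * np.asarray(c_tilde, dtype=float) + self.alpha


#: Uninformed third-level transform: beta = 0, alpha = 1/2, delta = 1/64.
UNINFORMED = PriorVarianceTransform(alpha=0.5, beta=0.0, delta=1.0 / 64.0)


def build_prior_covariance(c_tilde: np.ndarray, t: PriorVarianceTransform) -> GaussianDensity:
    """Third-level prior over group effective connectivity A2.

    Mean zero everywhere (for self-connections this is zero on the
    log-scaled parameterization, i.e. -1/2 Hz); diagonal covariance with
    variances from the transform, in column-major vectorization order.
    Exact-zero variances (alpha = 0 at an absent edge) are permitted and
    mean the connection is clamped to the prior mean.
    """
    c = np.asarray(c_tilde, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise InvalidParameterError("c_tilde must be square")
    n = c.shape[0]
    var = t.variance(c).copy()
    np.fill_diagonal(var, t.delta)
    v = var.flatten(order="F")
    if np.any(v < 0):
        raise InvalidTransformError("transform yields a negative variance")
    return GaussianDensity(np.zeros(n * n), np.diag(v), tuple(a_block_names(n)))


@dataclass(frozen=True)
class GroupModel:
    """Stacked subject data and specification of the group RFX model."""

    a1: np.ndarray  # (S * n^2,) stacked subject A-block posterior means
    subject_covs: tuple[np.ndarray, ...]  # per-subject A-block posterior covariances
    n: int
    third_prior: GaussianDensity  # over A2 (n^2)
    rfx_base_var: np.ndarray = field(default=None)  # diagonal of Q (n^2,)
    gamma_hyper_mean: float = 0.0
    gamma_hyper_var: float = 0.25

    def __post_init__(self) -> None:
        a1 = np.asarray(self.a1, dtype=float)
        object.__setattr__(self, "a1", a1)
        if a1.size % (self.n * self.n) != 0:
            raise InvalidParameterError("stacked vector length is not a multiple of n^2")
        if self.third_prior.dim != self.n * self.n:
            raise InvalidParameterError("third-level prior dimension mismatch")
        base = self.rfx_base_var
        if base is None:
            base = np.full(self.n * self.n, VAR_A_OFFDIAG)
            base[np.arange(self.n) * (self.n + 1)] = VAR_A_DIAG
        base = np.asarray(base, dtype=float)
        if base.shape != (self.n * self.n,) or np.any(base <= 0):
            raise InvalidParameterError("rfx_base_var must be positive of length n^2")
        object.__setattr__(self, "rfx_base_var", base)

    @property
    def n_subjects(self) -> int:
        return self.a1.size // (self.n * self.n)

    def subject_blocks(self) -> np.ndarray:
        return self.a1.reshape(self.n_subjects, self.n * self.n)


@dataclass(frozen=True)
class PEBResult:
    """Posterior of the group random-effects model."""

    posterior: GaussianDensity  # q(A2 | A1)
    gamma_mean: float
    gamma_var: float
    free_energy: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.free_energy):
            raise InvalidParameterError("free energy must be finite")


def stack_subject_means(posteriors: list[DCMPosterior], n: int | None = None) -> GroupModel:
    """Extract and stack the A-blocks of subject posteriors.

    Vectorization is column-major; subjects are stacked subject-major.
    Subject A-block covariances are recorded for the later downward
    Bayesian-model-reduction step (they do not enter the second-level
    likelihood).  The third-level prior defaults to the uninformed
    transform and can be replaced before inversion.
    """
    if not posteriors:
        raise MisalignedSubjectsError("no subjects supplied")
    names0 = posteriors[0].posterior.names
    if n is None:
        n_sq = sum(1 for nm in names0 if nm.startswith("A["))
        n = int(round(np.sqrt(n_sq)))
    block = a_block_names(n)
    means, covs = [], []
    for k, post in enumerate(posteriors):
        if post.posterior.names != names0:
            raise MisalignedSubjectsError(f"subject {k} has a different parameter naming")
        idx = post.posterior.index_of(block)
        marg = post.posterior.marginal(idx)
        means.append(marg.mean)
        covs.append(marg.cov)
    a1 = np.concatenate(means)
    third = build_prior_covariance(np.zeros((n, n)), UNINFORMED)
    return GroupModel(a1, tuple(covs), n, third)


def _group_log_marginal(model: GroupModel, gamma: float) -> tuple[float, np.ndarray, np.ndarray]:
    """ln p(A1 | gamma) plus conjugate posterior moments, per coordinate.

    With a diagonal third-level prior and Sigma_2 = exp(-gamma) Q
    diagonal, the A2 coordinates decouple: each is a Gaussian
    random-intercept model with S replicates.
    """
    S = model.n_subjects
    blocks = model.subject_blocks()  # (S, n^2)
    mu3 = model.third_prior.mean
    s3 = np.diag(model.third_prior.cov)
    e2 = np.exp(-gamma) * model.rfx_base_var  # per-coordinate RFX variance
    tau2 = 1.0 / e2

    post_prec = S * tau2 + np.where(s3 > 0, 1.0 / np.where(s3 > 0, s3, 1.0), np.inf)
    data_sum = blocks.sum(axis=0)
    post_mean = np.where(
        np.isinf(post_prec),
        mu3,
        (tau2 * data_sum + np.where(s3 > 0, mu3 / np.where(s3 > 0, s3, 1.0), 0.0)) / post_prec,
    )
    post_var = np.where(np.isinf(post_prec), 0.0, 1.0 / post_prec)

    # marginal: A1 coord-block ~ N(mu3 * 1, e2 I_S + s3 11^T)
    resid = blocks - mu3[None, :]
    rss = np.sum(resid**2, axis=0)
    rbar = resid.sum(axis=0)
    # matrix-determinant & Woodbury identities for e2 I + s3 11'
    logdet = S * np.log(e2) + np.log1p(S * s3 / e2)
    quad = rss / e2 - (s3 / (e2 * (e2 + S * s3))) * rbar**2
    ll = -0.5 * (S * model.n * model.n * np.log(2 * np.pi) + np.sum(logdet) + np.sum(quad))
    return float(ll), post_mean, post_var


def invert_group(model: GroupModel, fix_gamma: float | None = None) -> PEBResult:
    """Invert the group RFX model.

    The scalar log-precision hyperparameter ``gamma`` is optimized by
    maximizing ``ln p(A1 | gamma) + ln p(gamma)`` (variational Laplace
    with a single hyperparameter); conditional on the optimum the
    posterior over A2 is the exact conjugate form.  The reported free
    energy adds the Laplace entropy correction for ``gamma``.
    Deterministic.  Requires at least two subjects.
    """
    if model.n_subjects < 2:
        raise InsufficientReplicationError("group inversion requires at least 2 subjects")

    def objective(g: float) -> float:
        ll, _, _ = _group_log_marginal(model, g)
        return ll - 0.5 * (g - model.gamma_hyper_mean) ** 2 / model.gamma_hyper_var

    if fix_gamma is not None:
        g_hat = float(fix_gamma)
        g_var = 0.0
    else:
        res = minimize_scalar(lambda g: -objective(g), bounds=(-8.0, 8.0), method="bounded", options={"xatol": 1e-8})
        g_hat = float(res.x)
        h = 1e-4
        curv = (objective(g_hat + h) - 2 * objective(g_hat) + objective(g_hat - h)) / h**2
        g_var = float(-1.0 / curv) if curv < 0 else model.gamma_hyper_var

    ll, post_mean, post_var = _group_log_marginal(model, g_hat)
    F = ll
    if fix_gamma is None:
        F += -0.5 * (g_hat - model.gamma_hyper_mean) ** 2 / model.gamma_hyper_var
        if g_var > 0:
            F += 0.5 * (np.log(g_var / model.gamma_hyper_var) + 1.0 - g_var / model.gamma_hyper_var)
    q = GaussianDensity(post_mean, np.diag(post_var), tuple(a_block_names(model.n)))
    return PEBResult(q, g_hat, g_var, float(F))
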