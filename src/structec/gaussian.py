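"""Gaussian densities with named coordinates.

A :class:`GaussianDensity` (mean, covariance, parameter names) is the
common currency of the package: subject-level priors and posteriors,
group-level posteriors, empirical priors and every Bayesian model
reduction operate on it.  Covariances are allowed to be singular —
zero prior variance means "parameter clamped to its mean" — so
precisions are computed with a pseudo-inverse and log-determinants are
taken on the non-degenerate support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import pinvh

from .errors import DegenerateModelError, InvalidParameterError, MisalignedParametersError

__all__ = ["GaussianDensity", "gaussian_kl", "robust_precision", "logdet_psd"]

_EIG_TOL = 1e-10


def robust_precision(cov: np.ndarray) -> np.ndarray:
    """Pseudo-inverse of a symmetric PSD covariance (tolerant of singularity)."""
    return pinvh(np.asarray(cov, dtype=float), atol=1e-12)


def logdet_psd(mat: np.ndarray, tol: float = 1e-12) -> float:
    """Log pseudo-determinant of a symmetric PSD matrix (product of eigenvalues > tol)."""
    w = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    w = w[w > tol]
    if w.size == 0:
        return 0.0
    return float(np.sum(np.log(w)))


@dataclass(frozen=True)
class GaussianDensity:
    """Multivariate Gaussian N(mean, cov) with optional coordinate names."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 1:  # allow diagonal shorthand
            cov = np.diag(cov)
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "cov", cov)
        d = mu.size
        if cov.shape != (d, d):
            raise InvalidParameterError(f"covariance shape {cov.shape} != ({d},{d})")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(cov))):
            raise InvalidParameterError("non-finite Gaussian moments")
        if np.max(np.abs(cov - cov.T)) > 1e-8 * max(1.0, np.max(np.abs(cov))):
            raise InvalidParameterError("covariance is not symmetric")
        if np.min(np.linalg.eigvalsh(0.5 * (cov + cov.T))) < -_EIG_TOL * max(1.0, np.max(np.abs(cov))):
            raise InvalidParameterError("covariance has a significantly negative eigenvalue")
        names = tuple(self.names)
        if names and len(names) != d:
            raise InvalidParameterError("names length mismatch")
        object.__setattr__(self, "names", names)

    @property
    def dim(self) -> int:
        return self.mean.size

    def precision(self) -> np.ndarray:
        return robust_precision(self.cov)

    def index_of(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        if not self.names:
            raise MisalignedParametersError("density has no coordinate names")
        pos = {n: i for i, n in enumerate(self.names)}
        try:
            return np.array([pos[n] for n in names], dtype=int)
        except KeyError as e:
            raise MisalignedParametersError(f"unknown parameter name {e.args[0]!r}") from None

    def marginal(self, idx: np.ndarray) -> "GaussianDensity":
        idx = np.asarray(idx, dtype=int)
        names = tuple(self.names[i] for i in idx) if self.names else ()
        return GaussianDensity(self.mean[idx], self.cov[np.ix_(idx, idx)], names)

    def logpdf(self, x: np.ndarray) -> float:
        """Log density at ``x`` (covariance must be non-singular)."""
        d = self.dim
        sign, logdet = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise DegenerateModelError("singular covariance in logpdf")
        r = np.asarray(x, dtype=float) - self.mean
        return float(-0.5 * (d * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(self.cov, r)))


def gaussian_kl(q: GaussianDensity, p: GaussianDensity) -> float:
    """KL(q || p) between Gaussians sharing a support.

    Uses pseudo-inverse precision for ``p`` and support-restricted
    log-determinants, so exactly-clamped coordinates (zero variance in
    both densities) contribute nothing.
    """
    if q.dim != p.dim:
        raise MisalignedParametersError("dimension mismatch in KL")
    pp = p.precision()
    dmu = q.mean - p.mean
    ld_p = logdet_psd(p.cov)
    ld_q = logdet_psd(q.cov)
    rank = np.linalg.matrix_rank(0.5 * (p.cov + p.cov.T), tol=1e-12 * max(1.0, float(np.max(np.abs(p.cov)))))
    return float(0.5 * (np.trace(pp @ q.cov) + dmu @ pp @ dmu - rank + ld_p - ld_q))
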