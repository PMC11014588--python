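"""Empirical cross-spectral data features via multivariate autoregression.

Spectral-DCM inversion does not fit raw periodograms; it fits the
parametric spectrum of an MVAR model estimated from the observed BOLD
time series.  ``fit_mvar`` performs the ordinary-least-squares fit and
``mvar_csd`` evaluates the model's cross-spectral density

.. math::

    S(\\omega) = A(\\omega)^{-1} \\Sigma \\; A(\\omega)^{-\\dagger}\\,\\Delta t,
    \\qquad A(\\omega) = I - \\sum_k A_k e^{-i\\omega k \\Delta t},

on the analysis grid.  The ``\\Delta t`` factor converts the discrete-time
innovation covariance to a spectral density per unit frequency, so the
features live on the same (continuous-time) scale as the generative
model's predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IllConditionedDataError, NumericalSingularityError
from .forward import CrossSpectra, FrequencyGrid

__all__ = ["MVARModel", "fit_mvar", "mvar_csd", "detrend_columns"]

DEFAULT_ORDER = 8


@dataclass(frozen=True)
class MVARModel:
    """Fitted multivariate autoregressive model of order p."""

    order: int
    coefficients: np.ndarray  # (p, n, n); x_t ~ sum_k A_k x_{t-k}
    innovation_cov: np.ndarray  # (n, n) symmetric PSD
    n_samples: int

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficients, dtype=float)
        S = np.asarray(self.innovation_cov, dtype=float)
        object.__setattr__(self, "coefficients", A)
        object.__setattr__(self, "innovation_cov", 0.5 * (S + S.T))
        if self.order < 1 or A.shape != (self.order, S.shape[0], S.shape[0]):
            raise DomainError("inconsistent MVAR model shapes")

    @property
    def n(self) -> int:
        return self.innovation_cov.shape[0]


def detrend_columns(x: np.ndarray) -> np.ndarray:
    """Remove per-column mean and linear trend (resting-state convention)."""
    x = np.asarray(x, dtype=float)
    t = np.arange(x.shape[0], dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def fit_mvar(timeseries: np.ndarray, order: int = DEFAULT_ORDER, detrend: bool = True) -> MVARModel:
    """OLS fit of a vector autoregression x_t = sum_k A_k x_{t-k} + u_t.

    Columns are mean-centred (and by default linearly detrended) before
    fitting.  The innovation covariance uses the residual sum of squares
    with denominator ``T - p - n*p`` (small-sample degrees-of-freedom
    convention; switchable by post-hoc rescaling since it is a scalar
    factor).
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2:
        raise DomainError("timeseries must be 2-D (samples x regions)")
    T, n = x.shape
    if order < 1:
        raise DomainError("order must be >= 1")
    if T <= n * order + 1:
        raise IllConditionedDataError(f"need T > n*p + 1 samples (T={T}, n={n}, p={order})")
    x = detrend_columns(x) if detrend else x - x.mean(axis=0)

    sd = x.std(axis=0)
    if np.any(sd < 1e-12 * max(1.0, float(np.max(np.abs(x))))) or np.any(sd == 0):
        raise IllConditionedDataError("a column has (near-)zero variance")

    Y = x[order:]  # (T-p, n)
    lags = [x[order - k : T - k] for k in range(1, order + 1)]
    Z = np.concatenate(lags, axis=1)  # (T-p, n*p)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise IllConditionedDataError(f"regressor matrix rank {rank} < {Z.shape[1]}")
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)  # (n*p, n)
    resid = Y - Z @ B
    dof = max(T - order - n * order, 1)
    sigma = resid.T @ resid / dof
    coeffs = B.T.reshape(n, order, n).transpose(1, 0, 2)  # A_k = coeffs[k-1]
    return MVARModel(order, coeffs, sigma, T)


def mvar_csd(model: MVARModel, grid: FrequencyGrid, sampling_interval: float) -> CrossSpectra:
    """Parametric cross-spectral density of a fitted MVAR model."""
    if sampling_interval <= 0:
        raise DomainError("sampling interval must be positive")
    nyquist = 0.5 / sampling_interval
    if np.any(grid.hz >= nyquist):
        raise DomainError(f"grid extends to/beyond the Nyquist frequency {nyquist:g} Hz")
    om = grid.omega
    n = model.n
    phases = np.exp(-1j * om[:, None] * sampling_interval * np.arange(1, model.order + 1)[None, :])  # (F, p)
    Aw = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phases, model.coefficients)
    try:
        Ainv = np.linalg.solve(Aw, np.broadcast_to(np.eye(n), (om.size, n, n)))
    except np.linalg.LinAlgError:
        raise NumericalSingularityError("MVAR characteristic matrix singular on the grid") from None
    S = Ainv @ model.innovation_cov @ Ainv.conj().transpose(0, 2, 1) * sampling_interval
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectra(grid, S)
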