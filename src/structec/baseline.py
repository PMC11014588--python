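"""Structurally masked MVAR baseline for directed functional connectivity.

The comparison method treats structural connectivity as a template for
possible interactions: a directed autoregressive coefficient from region
i to region j is estimated only if a structural connection exists
between the two regions (self-lags are always included).  Per-target
least squares restricted to the masked predictors, with the reported
weight the sum of the per-lag coefficients.  Weights are unitless AR
coefficients; comparisons with effective connectivity (Hz) therefore use
scale-free statistics (correlation, sign agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IllConditionedDataError, MaskMismatchError
from .features import detrend_columns
from .peb import StructuralConnectivity

logger = logging.getLogger(__name__)

__all__ = ["DirectedFCEstimate", "fit_masked_mvar", "group_directed_fc"]


@dataclass(frozen=True)
class DirectedFCEstimate:
    """Masked AR estimate; ``weights[target, source]`` (unitless)."""

    weights: np.ndarray
    mask: np.ndarray
    order: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "mask", m)
        if w.shape != m.shape or w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DomainError("weights/mask must be matching square matrices")
        if np.any(w[~m] != 0.0):
            raise DomainError("weights outside the mask must be exactly zero")


def fit_masked_mvar(
    timeseries: np.ndarray,
    C: StructuralConnectivity,
    order: int = 1,
    detrend: bool = True,
) -> DirectedFCEstimate:
    """Per-target OLS restricted to structurally connected predictors.

    ``mask[target, source]`` is true on the diagonal (self-lags) and
    wherever the structural weight is positive.  A target with no
    allowed off-diagonal predictor is fitted on its self-lags only (a
    warning is logged, not an error).
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2:
        raise DomainError("timeseries must be 2-D")
    T, n = x.shape
    if C.n != n:
        raise DomainError("structural connectivity size does not match the series")
    if T <= n * order + 1:
        raise IllConditionedDataError(f"need T > n*p + 1 samples (T={T}, n={n}, p={order})")
    x = detrend_columns(x) if detrend else x - x.mean(axis=0)

    off = C.weights - np.diag(np.diag(C.weights))
    mask = (off > 0) | np.eye(n, dtype=bool)
    weights = np.zeros((n, n))
    Y = x[order:]
    lags = [x[order - k : T - k] for k in range(1, order + 1)]
    for j in range(n):
        sources = np.where(mask[j])[0]
        if sources.size == 1:
            logger.warning("region %d has no structurally allowed predictors; fitting self-lags only", j)
        Z = np.concatenate([L[:, sources] for L in lags], axis=1)  # (T-p, p*|sources|)
        beta, *_ = np.linalg.lstsq(Z, Y[:, j], rcond=None)
        summed = beta.reshape(order, sources.size).sum(axis=0)
        weights[j, sources] = summed
    return DirectedFCEstimate(weights, mask, order)


def group_directed_fc(estimates: list[DirectedFCEstimate]) -> np.ndarray:
    """Element-wise mean of subject-level masked AR weights."""
    if not estimates:
        raise DomainError("no estimates supplied")
    mask0 = estimates[0].mask
    for e in estimates[1:]:
        if e.mask.shape != mask0.shape or np.any(e.mask != mask0):
            raise MaskMismatchError("estimates use different masks")
    return np.mean([e.weights for e in estimates], axis=0)
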