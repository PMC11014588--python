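"""Recovery metrics: parity (correlation/RMSE) and three-class sign scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UndefinedCorrelationError

__all__ = ["ParityReport", "SignReport", "parity_metrics", "sign_macro_f1", "offdiag_values"]

SIGN_CLASSES = ("positive", "negative", "absent")
DEFAULT_ZERO_THRESHOLD = 0.05  # Hz


def offdiag_values(m: np.ndarray) -> np.ndarray:
    """Off-diagonal entries of a square matrix, column-major order."""
    m = np.asarray(m)
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return m.T[mask.T]  # column-major traversal


@dataclass(frozen=True)
class ParityReport:
    pearson_r: float
    rmse: float
    n_points: int
    scope: str


@dataclass(frozen=True)
class SignReport:
    macro_f1: float
    per_class: dict  # class -> {"precision", "recall", "f1"}
    threshold: float


def _scoped(estimate: np.ndarray, truth: np.ndarray, scope: str) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    if e.shape != t.shape:
        raise DomainError("estimate/truth shape mismatch")
    if scope == "offdiag":
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise DomainError("offdiag scope requires square matrices")
        return offdiag_values(e), offdiag_values(t)
    if scope == "all":
        return e.ravel(), t.ravel()
    raise DomainError(f"unknown scope {scope!r}")


def parity_metrics(estimate: np.ndarray, truth: np.ndarray, scope: str = "offdiag") -> ParityReport:
    """Pearson correlation and RMSE between estimate and truth.

    The default scope is off-diagonal entries only: self connections use
    a different parameterization and prior, so they are excluded from
    parity unless ``scope="all"`` is requested.
    """
    e, t = _scoped(estimate, truth, scope)
    if np.std(e) == 0 or np.std(t) == 0:
        raise UndefinedCorrelationError("zero-variance input; correlation undefined")
    r = float(np.corrcoef(e, t)[0, 1])
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    return ParityReport(r, rmse, e.size, scope)


def _classify(x: np.ndarray, threshold: float) -> np.ndarray:
    out = np.full(x.shape, "absent", dtype=object)
    out[x >= max(threshold, np.finfo(float).tiny)] = "positive"
    out[x <= -max(threshold, np.finfo(float).tiny)] = "negative"
    if threshold == 0:
        out[x > 0] = "positive"
        out[x < 0] = "negative"
    return out


def sign_macro_f1(
    estimate: np.ndarray,
    truth: np.ndarray,
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
    scope: str = "offdiag",
) -> SignReport:
    """Macro F1 over {positive, negative, absent} connection classes.

    Estimates within ``zero_threshold`` of zero are classed absent; the
    truth is classified with threshold zero (only exact zeros are
    absent).  A class with no true or predicted members scores F1 = 0,
    and the macro score is the unweighted mean over the three classes.
    """
    if zero_threshold < 0:
        raise DomainError("zero_threshold must be nonnegative")
    e, t = _scoped(estimate, truth, scope)
    pred = _classify(e, zero_threshold)
    true = _classify(t, 0.0)
    per_class = {}
    f1s = []
    for cls in SIGN_CLASSES:
        tp = int(np.sum((pred == cls) & (true == cls)))
        fp = int(np.sum((pred == cls) & (true != cls)))
        fn = int(np.sum((pred != cls) & (true == cls)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}
        f1s.append(f1)
    return SignReport(float(np.mean(f1s)), per_class, zero_threshold)
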