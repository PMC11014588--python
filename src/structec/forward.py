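"""Forward (generative) model of spectral DCM for resting-state fMRI.

A network of ``n`` neuronal populations evolves as a linear stochastic
state-space model

.. math::

    \\dot x(t) = A x(t) + v(t), \\qquad y(t) = h(x(t), \\theta_h) + e(t),

where ``A`` (Hz) is the effective-connectivity transition matrix, ``h`` a
linearized hemodynamic response and ``v``, ``e`` power-law noise
processes.  In the frequency domain the model predicts the cross-spectral
density (CSD) of the observed BOLD signals,

.. math::

    \\hat G_y(\\omega) = H(\\omega)\\,(i\\omega I - A)^{-1} G_v(\\omega)
        (-i\\omega I - A^T)^{-1} H(\\omega)^\\dagger + G_e(\\omega),

which is the quantity fitted to data features during inversion.

The hemodynamic response uses a linearized balloon model: per region, a
four-state linear system (vasodilatory signal, blood flow, venous volume,
deoxyhemoglobin) around its resting fixed point, with two free log-scaling
parameters per region modulating the signal-decay rate and the venous
transit time around canonical constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvalidParameterError, NumericalSingularityError

__all__ = [
    "FrequencyGrid",
    "EffectiveConnectivity",
    "HemodynamicParams",
    "NoiseSpectraParams",
    "CrossSpectra",
    "BalloonConstants",
    "BALLOON",
    "default_grid",
    "hemodynamic_transfer",
    "hemodynamic_state_matrix",
    "powerlaw_spectrum",
    "predicted_csd",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered analysis frequencies.

    Parameters
    ----------
    hz
        Strictly increasing linear frequencies in Hz, all positive.
    """

    hz: np.ndarray

    def __post_init__(self) -> None:
        hz = np.asarray(self.hz, dtype=float)
        object.__setattr__(self, "hz", hz)
        if hz.ndim != 1 or hz.size == 0:
            raise InvalidParameterError("frequency grid must be a non-empty vector")
        if not np.all(np.isfinite(hz)):
            raise InvalidParameterError("frequency grid contains non-finite values")
        if np.any(hz <= 0):
            raise DomainError("all grid frequencies must be positive")
        if np.any(np.diff(hz) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.hz

    def __len__(self) -> int:
        return self.hz.size


def default_grid(n_points: int = 32, f_min: float = 1.0 / 128.0, f_max: float = 0.25) -> FrequencyGrid:
    """Default resting-state analysis band: log-spaced points in [1/128, 0.25] Hz."""
    return FrequencyGrid(np.geomspace(f_min, f_max, n_points))


@dataclass(frozen=True)
class EffectiveConnectivity:
    """Effective-connectivity transition matrix A (Hz).

    Off-diagonal entries are directed inter-regional coupling rates; the
    diagonal holds (negative) self rate constants.  For simulation the
    matrix must be stable (all eigenvalues with negative real part); for
    likelihood evaluation marginal stability is tolerated.
    """

    weights: np.ndarray
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("effective connectivity must be square")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("effective connectivity has non-finite entries")
        labels = tuple(self.region_labels) or tuple(f"R{i}" for i in range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise InvalidParameterError("region_labels length mismatch")
        object.__setattr__(self, "region_labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def max_real_eigenvalue(self) -> float:
        return float(np.max(np.linalg.eigvals(self.weights).real))

    def is_stable(self, margin: float = 0.0) -> bool:
        return self.max_real_eigenvalue() < -margin


@dataclass(frozen=True)
class BalloonConstants:
    """Canonical constants of the linearized balloon/hemodynamic model.

    kappa : resting signal-decay rate (1/s)
    gamma : flow-dependent elimination rate (1/s)
    tau   : venous transit time (s)
    alpha : Grubb's vessel stiffness exponent
    e0    : resting oxygen extraction fraction
    v0    : resting venous volume fraction (percent signal units)
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 4.0

    @property
    def k1(self) -> float:
        return 7.0 * self.e0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.e0 - 0.2


BALLOON = BalloonConstants()


@dataclass(frozen=True)
class HemodynamicParams:
    """Per-region free hemodynamic parameters.

    ``decay`` and ``transit`` are unitless log-scaling factors applied to
    the canonical signal-decay rate and transit time; zero recovers the
    canonical response.
    """

    decay: np.ndarray
    transit: np.ndarray
    constants: BalloonConstants = field(default=BALLOON)

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.decay, dtype=float))
        t = np.atleast_1d(np.asarray(self.transit, dtype=float))
        if d.shape != t.shape or d.ndim != 1:
            raise InvalidParameterError("decay/transit must be equal-length vectors")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(t))):
            raise InvalidParameterError("hemodynamic parameters must be finite")
        object.__setattr__(self, "decay", d)
        object.__setattr__(self, "transit", t)

    @property
    def n(self) -> int:
        return self.decay.size

    @classmethod
    def canonical(cls, n: int) -> "HemodynamicParams":
        return cls(np.zeros(n), np.zeros(n))


@dataclass(frozen=True)
class NoiseSpectraParams:
    """Power-law parameters of endogenous fluctuations v and observation error e.

    Each spectrum is ``g(omega) = exp(log_amp) * omega**(-exp(log_exp))``
    with a per-region log-amplitude and one shared log-exponent per noise
    source; cross-region spectra are diagonal.
    """

    v_log_amp: np.ndarray
    v_log_exp: float
    e_log_amp: np.ndarray
    e_log_exp: float

    def __post_init__(self) -> None:
        va = np.atleast_1d(np.asarray(self.v_log_amp, dtype=float))
        ea = np.atleast_1d(np.asarray(self.e_log_amp, dtype=float))
        object.__setattr__(self, "v_log_amp", va)
        object.__setattr__(self, "e_log_amp", ea)
        if not (np.all(np.isfinite(va)) and np.all(np.isfinite(ea))):
            raise InvalidParameterError("noise log-amplitudes must be finite")
        for le in (self.v_log_exp, self.e_log_exp):
            # -inf encodes the flat-spectrum convention (exponent exactly 0)
            if np.isnan(le) or le == np.inf:
                raise InvalidParameterError("noise log-exponents must be finite or -inf")

    @classmethod
    def default(cls, n: int) -> "NoiseSpectraParams":
        return cls(np.zeros(n), 0.0, np.zeros(n), 0.0)


@dataclass(frozen=True)
class CrossSpectra:
    """Complex cross-spectral density on a frequency grid.

    ``matrices[k]`` is the Hermitian, positive-semidefinite n-by-n CSD at
    ``grid.hz[k]``.
    """

    grid: FrequencyGrid
    matrices: np.ndarray

    PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=complex)
        object.__setattr__(self, "matrices", m)
        if m.ndim != 3 or m.shape[0] != len(self.grid) or m.shape[1] != m.shape[2]:
            raise InvalidParameterError("matrices must be (n_freq, n, n)")

    @property
    def n(self) -> int:
        return self.matrices.shape[1]

    def is_hermitian(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.matrices - self.matrices.conj().transpose(0, 2, 1))) <= tol)

    def min_eigenvalue(self) -> float:
        return float(min(np.linalg.eigvalsh(0.5 * (m + m.conj().T)).min() for m in self.matrices))

    def validate(self) -> None:
        if not self.is_hermitian(1e-10):
            raise InvalidParameterError("cross-spectra are not Hermitian")
        if self.min_eigenvalue() < -self.PSD_TOL:
            raise InvalidParameterError("cross-spectra are not positive semidefinite")


def hemodynamic_state_matrix(decay: float, transit: float, c: BalloonConstants = BALLOON) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearized hemodynamic system (M, B, Cout) for one region.

    States are deviations from rest: (vasodilatory signal s, flow f-1,
    volume v-1, deoxyhemoglobin q-1).  Neuronal activity enters through B
    and BOLD output reads Cout @ state.
    """
    kappa = c.kappa * np.exp(decay)
    tau = c.tau * np.exp(transit)
    # d/df of f*E(f)/E0 at f=1, with E(f) = 1 - (1-E0)^(1/f)
    cf = 1.0 + (1.0 - c.e0) * np.log(1.0 - c.e0) / c.e0
    M = np.array(
        [
            [-kappa, -c.gamma, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0 / tau, -1.0 / (tau * c.alpha), 0.0],
            [0.0, cf / tau, -(1.0 / c.alpha - 1.0) / tau, -1.0 / tau],
        ]
    )
    B = np.array([1.0, 0.0, 0.0, 0.0])
    Cout = c.v0 * np.array([0.0, 0.0, c.k2 - c.k3, -(c.k1 + c.k2)])
    return M, B, Cout


def _transfer_from_rates(kappa: np.ndarray, tau: np.ndarray, om: np.ndarray, c: BalloonConstants) -> np.ndarray:
    """Batched linearized-balloon transfer: kappa/tau of shape (...,) ->
    H of shape (n_freq, ...)."""
    kappa = np.asarray(kappa, dtype=float)
    tau = np.asarray(tau, dtype=float)
    shape = kappa.shape
    cf = 1.0 + (1.0 - c.e0) * np.log(1.0 - c.e0) / c.e0
    M = np.zeros(shape + (4, 4))
    M[..., 0, 0] = -kappa
    M[..., 0, 1] = -c.gamma
    M[..., 1, 0] = 1.0
    M[..., 2, 1] = 1.0 / tau
    M[..., 2, 2] = -1.0 / (tau * c.alpha)
    M[..., 3, 1] = cf / tau
    M[..., 3, 2] = -(1.0 / c.alpha - 1.0) / tau
    M[..., 3, 3] = -1.0 / tau
    B = np.zeros(4)
    B[0] = 1.0
    Cout = c.v0 * np.array([0.0, 0.0, c.k2 - c.k3, -(c.k1 + c.k2)])
    F = om.size
    lhs = 1j * om.reshape((F,) + (1,) * len(shape) + (1, 1)) * np.eye(4) - M[None, ...]
    sol = np.linalg.solve(lhs, np.broadcast_to(B, lhs.shape[:-1])[..., None])
    return sol[..., 0] @ Cout


def hemodynamic_transfer(hparams: HemodynamicParams, grid: FrequencyGrid) -> np.ndarray:
    """Transfer function H(omega) from neuronal activity to BOLD, per region.

    Returns a complex array of shape ``(n_freq, n_regions)``.  Because the
    linearized hemodynamic system is strictly proper, ``|H| -> 0`` as
    ``omega -> inf``.
    """
    c = hparams.constants
    kappa = c.kappa * np.exp(hparams.decay)
    tau = c.tau * np.exp(hparams.transit)
    return _transfer_from_rates(kappa, tau, grid.omega, c)


def powerlaw_spectrum(log_amp: float, log_exp: float, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate g(omega) = exp(log_amp) * omega**(-exp(log_exp)) on the grid.

    ``log_exp = -inf`` encodes a flat spectrum (exponent exactly 0).
    """
    if not np.isfinite(log_amp):
        raise InvalidParameterError("log_amp must be finite")
    exponent = np.exp(log_exp)  # exp(-inf) == 0 -> flat spectrum
    om = grid.omega
    return np.exp(log_amp) * om ** (-exponent)


def _noise_csd(nparams: NoiseSpectraParams, grid: FrequencyGrid) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal G_v(omega), G_e(omega) as (F, n) positive arrays."""
    om = grid.omega
    gv = np.exp(nparams.v_log_amp)[None, :] * (om ** (-np.exp(nparams.v_log_exp)))[:, None]
    ge = np.exp(nparams.e_log_amp)[None, :] * (om ** (-np.exp(nparams.e_log_exp)))[:, None]
    return gv, ge


def predicted_csd(
    A: EffectiveConnectivity,
    hparams: HemodynamicParams,
    nparams: NoiseSpectraParams,
    grid: FrequencyGrid,
) -> CrossSpectra:
    """Predicted BOLD cross-spectral density of the linear state-space model.

    Evaluates ``H (i w I - A)^-1 G_v (-i w I - A^T)^-1 H^† + G_e`` at every
    grid frequency via batched linear solves (no explicit inverses).
    Marginally stable ``A`` is accepted — the likelihood must remain
    evaluable during inversion — but a singular ``(i w I - A)`` raises
    :class:`NumericalSingularityError` naming the frequency.
    """
    n = A.n
    if hparams.n != n or nparams.v_log_amp.size != n or nparams.e_log_amp.size != n:
        raise InvalidParameterError("region count mismatch between A, hparams, nparams")
    om = grid.omega
    H = hemodynamic_transfer(hparams, grid)  # (F, n)
    gv, ge = _noise_csd(nparams, grid)  # (F, n) each

    lhs = 1j * om[:, None, None] * np.eye(n) - A.weights  # (F, n, n)
    try:
        Minv = np.linalg.solve(lhs, np.broadcast_to(np.eye(n), (om.size, n, n)))
    except np.linalg.LinAlgError:
        bad = [f for f, L in zip(grid.hz, lhs) if abs(np.linalg.det(L)) < 1e-300]
        f_bad = bad[0] if bad else float("nan")
        raise NumericalSingularityError(f"(i*omega*I - A) singular at frequency {f_bad:g} Hz") from None
    if not np.all(np.isfinite(Minv)):
        k = int(np.argwhere(~np.isfinite(Minv))[0, 0])
        raise NumericalSingularityError(f"(i*omega*I - A) singular at frequency {grid.hz[k]:g} Hz")

    # X X^† = Minv diag(gv) Minv^†, then sandwich with diag(H)
    core = (Minv * gv[:, None, :]) @ Minv.conj().transpose(0, 2, 1)
    G = H[:, :, None] * core * H.conj()[:, None, :]
    G += np.eye(n)[None, :, :] * ge[:, None, :]
    G = 0.5 * (G + G.conj().transpose(0, 2, 1))  # enforce exact Hermitian symmetry
    return CrossSpectra(grid, G)


def predicted_csd_many(
    weights: np.ndarray,
    decay: np.ndarray,
    transit: np.ndarray,
    v_amp: np.ndarray,
    v_exp: np.ndarray,
    e_amp: np.ndarray,
    e_exp: np.ndarray,
    grid: FrequencyGrid,
    constants: BalloonConstants = BALLOON,
) -> np.ndarray:
    """Vectorized CSD prediction for a batch of parameter settings.

    ``weights`` is (P, n, n); ``decay``/``transit``/``v_amp``/``e_amp``
    are (P, n); ``v_exp``/``e_exp`` are (P,).  Returns a complex array
    (P, n_freq, n, n).  Used for finite-difference Jacobians, where P
    forward evaluations per iteration dominate the inversion cost.
    """
    c = constants
    weights = np.asarray(weights, dtype=float)
    P, n, _ = weights.shape
    om = grid.omega
    F = om.size
    H = _transfer_from_rates(c.kappa * np.exp(decay), c.tau * np.exp(transit), om, c)  # (F, P, n)
    gv = np.exp(v_amp)[None, :, :] * (om[:, None] ** (-np.exp(v_exp))[None, :])[:, :, None]  # (F, P, n)
    ge = np.exp(e_amp)[None, :, :] * (om[:, None] ** (-np.exp(e_exp))[None, :])[:, :, None]
    lhs = 1j * om[:, None, None, None] * np.eye(n) - weights[None, :, :, :]  # (F, P, n, n)
    Minv = np.linalg.solve(lhs, np.broadcast_to(np.eye(n), (F, P, n, n)))
    core = (Minv * gv[:, :, None, :]) @ Minv.conj().transpose(0, 1, 3, 2)
    G = H[:, :, :, None] * core * H.conj()[:, :, None, :]
    G += np.eye(n) * ge[:, :, None, :]
    G = 0.5 * (G + G.conj().transpose(0, 1, 3, 2))
    return G.transpose(1, 0, 2, 3)
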