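"""Synthetic-data generator for the in-silico validation design.

Data are generated from the hierarchical model itself: a sparse
symmetric structural connectome, group-level effective connectivity
drawn as a standard Gaussian scaled by the square root of the linear
prior-variance transform of normalized structural connectivity,
subject-level effective connectivity as Gaussian deviations from the
group matrix, and BOLD-like time series obtained by Euler-Maruyama
integration of the linear state-space model with smoothed (one-pole
low-pass) Gaussian endogenous fluctuations, the same linearized
hemodynamics as the forward model, decimation to the sampling interval,
and additive white observation noise calibrated to a per-region
signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InfeasibleDensityError, InstabilityError, InvalidTransformError
from .forward import EffectiveConnectivity, HemodynamicParams, hemodynamic_state_matrix
from .peb import StructuralConnectivity, normalize_structural

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "sample_structural",
    "sample_group_ec",
    "sample_subject_ec",
    "ensure_stable",
    "simulate_bold",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the in-silico design.

    Defaults: a 6-region network, 50 instantiations of S = 10 subjects,
    BOLD-like series of 1200 samples at a 0.72 s sampling interval,
    signal-to-noise ratio 1, ground-truth transform (alpha, beta) =
    (0.02, 0.25) with between-subject deviation sd 0.1 and self
    connections of -0.5 Hz.
    """

    n_regions: int = 6
    subjects: int = 10
    instantiations: int = 50
    snr: float = 1.0
    alpha_true: float = 0.02
    beta_true: float = 0.25
    rfx_sd: float = 0.1
    self_value: float = -0.5
    n_samples: int = 1200
    sampling_interval: float = 0.72
    integration_step: float = 0.05
    structural_density: float = 0.5
    weight_range: tuple[float, float] = (0.2, 1.0)
    fluctuation_tau: float = 2.0  # one-pole smoothing time constant (s)
    burn_in: float = 64.0  # settling time discarded before recording (s)
    stability_margin: float = 0.05  # Hz
    resample_group_ec: bool = True  # fresh group EC per instantiation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise DomainError("snr must be positive")
        if self.n_samples * self.sampling_interval < 128.0:
            raise DomainError("series too short for the lowest analysis frequency (need >= 128 s)")
        if self.self_value >= 0:
            raise DomainError("self connections must be negative (stabilizing)")
        if self.integration_step <= 0 or self.sampling_interval <= 0:
            raise DomainError("time steps must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth of one instantiation, with full seed provenance."""

    structural: StructuralConnectivity
    a2_true: EffectiveConnectivity
    subject_ecs: tuple[EffectiveConnectivity, ...]
    seeds: dict = field(default_factory=dict)


def sample_structural(
    n: int,
    density: float = 0.5,
    weight_range: tuple[float, float] = (0.2, 1.0),
    seed: int | np.random.Generator = 0,
) -> StructuralConnectivity:
    """Sparse symmetric nonnegative connectome with connected support.

    Exactly ``round(density * n(n-1)/2)`` undirected edges: a uniform
    random spanning tree first (guaranteeing connectivity), then the
    remaining edges drawn without replacement; weights uniform on
    ``weight_range``.
    """
    if not (0 < density <= 1):
        raise DomainError("density must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(round(density * n * (n - 1) / 2))
    if m < n - 1:
        raise InfeasibleDensityError(f"{m} edges cannot connect {n} regions")
    # random spanning tree via a Prufer sequence
    if n == 2:
        tree = [(0, 1)]
    else:
        prufer = rng.integers(0, n, size=n - 2)
        degree = np.ones(n, dtype=int)
        for v in prufer:
            degree[v] += 1
        tree = []
        ptr = 0
        leaves = sorted(np.where(degree == 1)[0].tolist())
        import heapq

        heapq.heapify(leaves)
        for v in prufer:
            leaf = heapq.heappop(leaves)
            tree.append((leaf, int(v)))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, int(v))
        u, v = heapq.heappop(leaves), heapq.heappop(leaves)
        tree.append((u, v))
    edges = {tuple(sorted(e)) for e in tree}
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    remaining = [p for p in all_pairs if p not in edges]
    extra = m - len(edges)
    if extra > 0:
        pick = rng.choice(len(remaining), size=extra, replace=False)
        edges |= {remaining[k] for k in pick}
    C = np.zeros((n, n))
    lo, hi = weight_range
    for i, j in sorted(edges):
        w = rng.uniform(lo, hi)
        C[i, j] = C[j, i] = w
    return StructuralConnectivity(C)


def sample_group_ec(
    c_tilde: np.ndarray,
    alpha_true: float,
    beta_true: float,
    self_value: float = -0.5,
    seed: int | np.random.Generator = 0,
) -> EffectiveConnectivity:
    """Group effective connectivity: standard Gaussian scaled by the
    square root of the linear transform of normalized structural
    connectivity, independently per directed edge; fixed diagonal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(c_tilde, dtype=float)
    n = c.shape[0]
    var = beta_true * c + alpha_true
    if np.any(var < -1e-15):
        raise InvalidTransformError("transform yields a negative variance at some edge")
    var = np.clip(var, 0.0, None)
    z = rng.standard_normal((n, n))
    A = np.sqrt(var) * z
    np.fill_diagonal(A, self_value)
    return EffectiveConnectivity(A)


def sample_subject_ec(
    a2: EffectiveConnectivity,
    rfx_sd: float,
    seed: int | np.random.Generator = 0,
) -> EffectiveConnectivity:
    """Subject deviation: iid Gaussian perturbation of the off-diagonal
    entries; the diagonal passes through unperturbed.  Stability is not
    enforced here (see :func:`ensure_stable`)."""
    if rfx_sd < 0:
        raise DomainError("rfx_sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a2.n
    eps = rfx_sd * rng.standard_normal((n, n))
    np.fill_diagonal(eps, 0.0)
    return EffectiveConnectivity(a2.weights + eps, a2.region_labels)


def ensure_stable(A: EffectiveConnectivity, margin: float = 0.05) -> EffectiveConnectivity:
    """Uniformly deepen the diagonal until the spectral abscissa is at
    most ``-margin``; already-stable matrices are returned unchanged.
    Idempotent (a second application is a no-op)."""
    if margin <= 0:
        raise DomainError("margin must be positive")
    m = A.max_real_eigenvalue()
    if m <= -margin:
        return A
    w = A.weights.copy()
    w[np.diag_indices(A.n)] -= m + margin  # shifts every eigenvalue by exactly -(m + margin)
    return EffectiveConnectivity(w, A.region_labels)


def _joint_system(A: EffectiveConnectivity, hparams: HemodynamicParams, tau_c: float):
    """Linear SDE for [OU inputs (n); neuronal x (n); hemodynamic states (4n)].

    Returns (M, noise_rows, output_matrix) where white noise enters only
    the OU coordinates and BOLD reads output_matrix @ state.
    """
    n = A.n
    d = 2 * n + 4 * n
    M = np.zeros((d, d))
    M[:n, :n] = -np.eye(n) / tau_c  # one-pole smoothing of white input
    M[n : 2 * n, :n] = np.eye(n)  # smoothed input drives the neuronal states
    M[n : 2 * n, n : 2 * n] = A.weights
    Cout = np.zeros((n, d))
    for r in range(n):
        Mr, Br, Cr = hemodynamic_state_matrix(hparams.decay[r], hparams.transit[r], hparams.constants)
        s = 2 * n + 4 * r
        M[s : s + 4, s : s + 4] = Mr
        M[s : s + 4, n + r] = Br
        Cout[r, s : s + 4] = Cr
    return M, np.arange(n), Cout


def simulate_bold(
    A: EffectiveConnectivity,
    hparams: HemodynamicParams,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """BOLD-like series (n_samples x n) for one subject.

    Euler-Maruyama integration at a step snapped to an integer divisor of
    the sampling interval; a burn-in period is discarded so the recorded
    segment is (approximately) stationary.  Observation noise is white
    Gaussian with per-region sd equal to signal sd divided by ``snr``
    (``snr = inf`` disables it).  Deterministic per seed.
    """
    if not A.is_stable(0.0):
        raise DomainError("effective connectivity must be stable for simulation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = A.n
    decim = max(int(round(config.sampling_interval / config.integration_step)), 1)
    dt = config.sampling_interval / decim
    n_burn = int(np.ceil(config.burn_in / dt))
    n_steps = n_burn + config.n_samples * decim
    M, noise_idx, Cout = _joint_system(A, hparams, config.fluctuation_tau)
    d = M.shape[0]
    Phi = np.eye(d) + dt * M  # Euler one-step propagator
    state = np.zeros(d)
    sqdt = np.sqrt(dt)
    y = np.empty((config.n_samples, n))
    rec = 0
    noise = rng.standard_normal((n_steps, n))
    for k in range(n_steps):
        state = Phi @ state
        state[noise_idx] += sqdt * noise[k]
        if k % 256 == 0 and not np.all(np.isfinite(state)):
            raise InstabilityError(f"integration diverged at step {k} (t = {k * dt:.2f} s)")
        if k >= n_burn and (k - n_burn) % decim == decim - 1:
            y[rec] = Cout @ state
            rec += 1
    if not np.all(np.isfinite(y)):
        bad = int(np.argwhere(~np.isfinite(y))[0, 0])
        raise InstabilityError(f"integration diverged near sample {bad}")
    sd = y.std(axis=0)
    if np.isfinite(config.snr):
        y = y + (sd / config.snr) * rng.standard_normal(y.shape)
    return y


def generate_dataset(config: SimulationConfig, instantiation: int = 0):
    """One instantiation of the in-silico design.

    The structural connectome depends only on the master seed, so it is
    shared across instantiations; group effective connectivity, subject
    deviations and noise realizations are drawn from per-instantiation
    seed streams (recorded in the returned provenance).  Returns
    ``(GroundTruth, [series_1, ..., series_S])``.
    """
    ss = np.random.SeedSequence(config.seed)
    struct_seed, inst_root = ss.spawn(2)
    C = sample_structural(config.n_regions, config.structural_density, config.weight_range, np.random.default_rng(struct_seed))
    c_tilde = normalize_structural(C)

    inst_seed = inst_root.spawn(instantiation + 1)[-1]
    group_stream, *subj_streams = inst_seed.spawn(1 + 2 * config.subjects)
    ec_stream = group_stream if config.resample_group_ec else struct_seed.spawn(1)[0]
    a2 = sample_group_ec(
        c_tilde,
        config.alpha_true,
        config.beta_true,
        config.self_value,
        np.random.default_rng(ec_stream),
    )
    hparams = HemodynamicParams.canonical(config.n_regions)
    subject_ecs = []
    series = []
    for s in range(config.subjects):
        ec = sample_subject_ec(a2, config.rfx_sd, np.random.default_rng(subj_streams[2 * s]))
        ec = ensure_stable(ec, config.stability_margin)
        subject_ecs.append(ec)
        series.append(simulate_bold(ec, hparams, config, np.random.default_rng(subj_streams[2 * s + 1])))
    seeds = {
        "master": config.seed,
        "instantiation": instantiation,
        "structural": struct_seed.entropy,
    }
    gt = GroundTruth(C, a2, tuple(subject_ecs), seeds)
    return gt, series
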