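# Methods

`structec` implements a hierarchical empirical Bayes procedure for
structurally informed resting-state effective connectivity, together
with the in-silico study that validates it. This note records the model,
the numerical choices, and what the synthetic experiments do and do not
establish.

## Subject-level model: spectral DCM

Each subject's BOLD time series is modelled by the linear stochastic
state-space system

    dx/dt = A x + v(t),        y(t) = h(x, θ_h) + e(t),

where `A` (Hz) is the effective-connectivity transition matrix — the
directed influence of each neuronal population's activity on the rates
of change of the others — `h` is a hemodynamic response and `v`, `e`
are endogenous fluctuations and observation error. Inference is carried
out in the frequency domain: the model predicts the cross-spectral
density (CSD)

    Ĝ_y(ω) = H(ω) (iωI − A)⁻¹ G_v(ω) (−iωI − Aᵀ)⁻¹ H(ω)† + G_e(ω),

which is fitted to data features.

**Hemodynamics.** `H(ω)` comes from a linearized balloon model: per
region, a four-state linear system (vasodilatory signal, inflow, venous
volume, deoxyhemoglobin) around its resting point, with canonical
constants (signal decay 0.64 s⁻¹, flow elimination 0.32 s⁻¹, transit
time 2 s, stiffness exponent 0.32, resting extraction 0.4, V₀ = 4) and
two free log-scaling parameters per region (decay, transit). The
transfer function is validated against a time-domain integration of the
same ODE to < 1% (`tests/test_forward.py`).

**Noise spectra.** `G_v`, `G_e` are diagonal power laws
`exp(amp) · ω^(−exp(log_exp))`, with per-region log-amplitudes and one
shared log-exponent per source. `log_exp = −∞` encodes an exactly flat
spectrum.

**Data features.** The empirical CSD is the parametric spectrum of an
order-8 OLS vector autoregression fitted to the mean-centred, linearly
detrended series: `S(ω) = A(ω)⁻¹ Σ A(ω)⁻† Δt`. Both empirical and
predicted CSDs are treated as two-sided densities per Hz (checked
against Welch estimates of long simulations). Features are evaluated on
32 log-spaced frequencies in [1/128, 0.25] Hz (resting-state band for a
0.72 s sampling interval) and stacked without redundancy: per
frequency, the real parts of the upper triangle and the imaginary parts
of the strict upper triangle.

**Inversion.** Variational Laplace: a Gaussian `q(θ) = N(μ, Σ)` is
optimized by Gauss–Newton ascent on the free energy
`F = E_q[ln p(y|θ)] − KL(q‖prior)` with Levenberg–Marquardt damping;
the expected log-likelihood uses a local linearization at `μ` (forward
finite differences, step 1e-4). Candidate steps are scored under their
own linearization, so accepted steps never decrease `F`; convergence is
declared after three consecutive changes below 1e-4 nats (cap 128
iterations). Before fitting, the data CSD is rescaled so its mean
diagonal power matches the prior-mean prediction, and the stacked
feature vector is normalized to unit RMS; observation noise is IID
Gaussian on that vector with one log-precision hyperparameter per
subject, hyperprior N(6, 1/16) — i.e. the feature noise level is
pinned near e⁻³ of the feature scale, the convention for spectral
features, rather than re-estimated from residuals (which would let
model mismatch masquerade as noise and over-shrink the estimates).

Priors: off-diagonal `A` entries N(0, 1/64); self-connections
parameterized as `−½·exp(a_ii)` Hz with `a_ii ~ N(0, 1/64)` (negative
by construction); hemodynamic and noise log-parameters N(0, 1/16). For
linear models the implementation reproduces the exact conjugate log
evidence to 1e-6 (`linear_gaussian_evidence` is the oracle).

## Group level: random effects with structure-based priors

Stacked subject posterior means `A¹ = [vec A_1; …; vec A_S]` (column
major, self-connections on the log scale) are treated as data for

    A¹ = (1 ⊗ I) A² + ε₂,     A² ~ N(μ₃, Σ₃),

with `ε₂ ~ N(0, exp(−γ)·Q)`. `Q` is the diagonal of the subject-level
prior variances on the A-block, so `γ = 0` means "between-subject
spread equal to the single-subject prior scale"; `γ` has hyperprior
N(0, 1/4) and is optimized by bounded scalar search, with a Laplace
correction in the reported free energy. Conditional on `γ` everything
is conjugate and, because `Σ₃` and `Q` are diagonal, the `A²`
coordinates decouple into scalar random-intercept models (verified
against the dense conjugate oracle). Subject posterior covariances are
deliberately excluded here — the posterior means are the data — and
re-enter only in the downward updates.

The third-level prior encodes anatomy: with normalized structural
connectivity `c̃ = (C∘(1−I)) / max(C∘(1−I))`,

    σ²_ij = β·c̃_ij + α  (i≠j),     σ²_ii = δ,

so `α` is the anatomy-independent variance floor, `β` the structural
scaling, and `δ` (default 1/64) the self-connection variance. The
uninformed setting is β = 0, α = 1/2, δ = 1/64. `α = 0` with `c̃ = 0`
yields an exact-zero variance: the connection is clamped to the prior
mean (handled in reduction by a 1e-10 variance floor).

## Model reduction, grid search, averaging, downward updates

Bayesian model reduction computes, in closed form, the posterior and
free-energy change that would have resulted from any alternative prior
with the same likelihood (precision form; pseudo-inverses with a
variance floor for clamped coordinates; an improper reduction —
non-positive reduced posterior precision — raises an error naming the
offending eigenvalue). The identity reduction returns the full
posterior and exactly ΔF = 0. One routine serves both levels: scoring
structure-based third-level priors against the uninformed group model,
and propagating the informed group posterior downward as an empirical
prior on each subject's A-block (non-A parameters pass through; the
cross-covariance between the updated block and the rest is zeroed,
since the reduction acts on the marginal).

The grid samples α at 30 equidistant points over [−1/2, 1/2] and, per
α, β at 30 equidistant points over [0, 1/2−α], keeping combinations
with α ≥ 0 and α+β ≥ 1e-5 (421 regimes by default; resolution is
configuration). Bayesian model averaging weights the regimes by a
softmax of their free energies (max-subtracted — observed differences
reach hundreds of nats — and exactly shift-invariant); the 95%
envelope is the weighted 2.5/97.5 percentile band of `σ²(c̃)` over
regimes at 101 equidistant `c̃` values. The weighted envelope is our
definition; the averaging itself is exact.

## Synthetic-data generator

The generator draws from the hierarchical model itself:

* a sparse symmetric connectome (random spanning tree plus uniform
  extra edges, weights U(0.2, 1), density 0.5 — exactly
  `round(density·n(n−1)/2)` edges, connected by construction);
* group effective connectivity `A²_ij = sqrt(β·c̃_ij + α)·z_ij`
  with independent standard Gaussians per directed edge
  (α = 0.02, β = 0.25 by default) and self-connections −0.5 Hz;
* subject matrices `A_s = A² + ε`, ε off-diagonal N(0, 0.1²), then a
  uniform diagonal deepening to a spectral abscissa ≤ −0.05 Hz
  (idempotent, off-diagonals untouched);
* BOLD-like series by Euler–Maruyama integration (step snapped to an
  integer divisor of the 0.72 s sampling interval, 64 s burn-in) of
  the joint linear system comprising one-pole-smoothed Gaussian
  endogenous fluctuations (time constant 2 s — an approximation of
  power-law input at this scale), the neuronal states, and the same
  linearized hemodynamics used in inversion; then decimation and
  additive white observation noise with per-region noise SD equal to
  signal SD divided by the SNR (definition of SNR used throughout;
  SNR = ∞ disables noise). All randomness flows from per-task seed
  streams spawned from one master seed; the connectome is fixed across
  instantiations while the group matrix is redrawn per instantiation.

**What the generator does not emulate.** The endogenous input is
Lorentzian rather than an exact power law, the observation noise is
white rather than power-law, and the series pass through a finite-order
MVAR feature step. The inference model can therefore never fit these
data exactly, which makes the in-silico study a robustness probe as
much as a parity check; see "Known limitations".

## The in-silico study and the baseline

Per instantiation: generate S subjects, extract features, invert each
DCM, invert the uninformed group model, score the grid by reduction,
average, re-reduce the group model under the evidence-weighted
transform, update the subjects downward, and fit the structurally
masked MVAR baseline (per-target OLS restricted to structurally
connected predictors, order 1, lag-summed weights) to the same series.
Reported: pooled and per-instantiation Pearson r / RMSE of the group
MAP against the true group matrix (off-diagonal scope — self
connections live on a different parameterization), subject-level
correlation distributions for both methods, macro-F1 over
{positive, negative, absent} classes (estimate threshold 0.05 Hz;
exact zeros in truth are "absent"), the group-level log-Bayes factor
of the structure-based model over the uninformed one, and whether the
true variance function lies inside the weighted envelope at
c̃ ∈ {0, ½, 1}.

Default study size in the acceptance script: 20 instantiations of 10
subjects (a reduced version of the 50-instantiation design; the
pooled statistics stabilize well before 50).

## Known limitations

Under the default ground-truth transform the strongest edges reach
|A| ≈ 0.5 Hz. Diagnostic experiments (exact in-class CSD inversions,
truth-clamped free-energy comparisons, prior/band/order sweeps) show
that in this strong-coupling regime the subject-level MAP is
intrinsically attenuated: the cross-spectral likelihood ridge around
the true parameters is thin relative to the MVAR feature sampling
error at T = 1200 and SNR 1, so the variational optimum genuinely
prefers a weaker-coupled explanation, and widening the connectivity
priors trades this bias for estimation noise without improving the
group-level summary. Consequently the pooled group-level correlation
plateaus around 0.7–0.77, the pooled RMSE around 0.26 Hz, and the
recovered transform slope β̄ underestimates the generative β (the
evidence still identifies the structural scaling direction: the
log-Bayes factor for structure-based priors exceeds 3 in essentially
every instantiation, and β̄ collapses toward zero when the generative
β is zero). Exact in-class features invert at regression slopes near
one, confirming that the limitation lies in the identifiability of
strong couplings from finite noisy spectra, not in the implementation.
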