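# structec

Structurally informed hierarchical empirical Bayes modelling of
resting-state effective connectivity.

## The problem

Anatomical (structural) connectivity — the network of nerve tracts
between brain regions — plausibly constrains *effective* connectivity,
the directed influence one neuronal population exerts on another. This
package implements a hierarchical Bayesian procedure that makes that
idea testable: structural connectivity does not fix the effective
connections themselves, but scales how *variable* they are allowed to
be a priori, and the evidence for that assumption is measured on data.

It is aimed at researchers working with resting-state fMRI time series
and tractography-derived connectomes who want (i) subject- and
group-level effective-connectivity estimates, (ii) a principled
evidence comparison between structure-based and uninformative priors,
and (iii) a fully synthetic validation harness.

## The model

At the subject level, spectral dynamic causal modelling (DCM): a linear
state-space model

    dx/dt = A x + v(t),      y = h(x, θ_h) + e(t)

whose frequency-domain prediction

    Ĝ_y(ω) = H(ω)(iωI − A)⁻¹ G_v(ω)(−iωI − Aᵀ)⁻¹ H(ω)† + G_e(ω)

is fitted by variational Laplace to the cross-spectral density of the
observed series (estimated parametrically from an order-8 MVAR model).
`A` (Hz) is the effective connectivity; `H` is a linearized balloon
hemodynamic transfer; `G_v`, `G_e` are power-law noise spectra.

Above it, a random-effects model over the stacked subject posterior
means `A¹ = (1⊗I)A² + ε₂` with a third-level prior `A² ~ N(μ₃, Σ₃)`
whose variances are a linear function of normalized structural
connectivity `c̃`:

    σ²_ij = β·c̃_ij + α   (i ≠ j),      σ²_ii = δ.

A grid of (α, β) regimes is scored analytically by Bayesian model
reduction against the model inverted under uninformative priors
(β = 0, α = ½, δ = 1/64); Bayesian model averaging with softmax
(free-energy) weights yields an evidence-weighted transform; the group
model is re-reduced under it, and the resulting posterior propagates
downward as an empirical prior that re-evaluates every subject — all in
closed form.

## Worked example

Simulate one synthetic cohort, invert one subject, and score it:

    $ structec --seed 3 --out demo simulate
    wrote 10 subjects to demo

    $ structec --seed 3 --out demo invert demo/subject001_bold.tsv
    F = 1817.017, converged = True; wrote demo/subject001_bold_posterior.json

`F` is the variational free energy (nats) of the subject's spectral
DCM — the quantity used for all model comparisons. The in-silico
study (generate cohorts, invert everyone, grid/BMA, baseline
comparison) runs with, e.g., a 4-instantiation configuration:

    $ printf 'simulation:\n  instantiations: 4\n' > small.yaml
    $ structec --config small.yaml --seed 3 --out demo run-insilico
    pooled r = 0.752, RMSE = 0.280; wrote demo/insilico_report.json

meaning: across instantiations, estimated group connections correlate
with the generative truth at r ≈ 0.75 with a root-mean-square error of
≈ 0.28 Hz on the off-diagonal couplings. The report also contains the
per-instantiation log-Bayes factors of structure-based over
uninformative priors (here, tens of nats — decisive on the
conventional 3-nat threshold), the averaged transform (ᾱ, β̄) with its
95% envelope, and the masked-MVAR baseline metrics on the same data.

The library surface mirrors the pipeline: `simulate.generate_dataset`,
`features.fit_mvar` / `features.mvar_csd`, `invert.invert_dcm`,
`peb.invert_group`, `bmr.score_grid` / `bmr.bma_average` /
`bmr.update_subjects`, `baseline.fit_masked_mvar`, and
`experiment.run_insilico`; see `docs/methods.md` for the model details
and numerical choices.

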