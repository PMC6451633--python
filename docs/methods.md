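# Methods

## Model

Subjects `i = 1..n_j` are nested in groups `j = 1..J`.  Each group belongs to
one of `K` latent populations; membership indicators `z_j ~ Multinomial(π)`.
Conditional on membership `k`, subject `(i, j)` has hazard
`λ0(t) w_k exp(X_ijᵀβ)` with a non-parametric baseline.  Observables per
subject are `(t_ij, δ_ij, X_ij)` with `t_ij = min(T*_ij, C_ij)` and
censoring assumed non-informative given covariates and frailty.  The
complete-data likelihood factors into a multinomial part (π) and a survival
part (w, β, λ0); integrating the memberships out gives the observable
log-likelihood

```
l(θ) = Σ_ij δ_ij log(λ0(t_ij) e^{X'β}) + Σ_j log Σ_k π_k w_k^{D_j} exp(−w_k A_j)
```

with `D_j` the group's event count and `A_j = Σ_i Λ0(t_ij) e^{X'β}` its
unit-frailty cumulative-hazard exposure.  Because the baseline is a step
function (NPML), `λ0(t)` at an event time is read as the jump height of the
Breslow estimate at that time; between jumps the cumulative baseline is a
right-continuous step.  The model is invariant under `w → c·w`,
`Λ0 → Λ0/c`, so only frailty *ratios* are identified; the package reports
`w/min(w)` post hoc and sorts populations by ascending w.

## EM algorithm

Each iteration: (1) E-step — closed-form posterior memberships
`α_jk ∝ π_k w_k^{D_j} exp(−w_k A_j)`, computed by log-sum-exp; (2) M-step —
`π̂_k = mean_j α_jk`; `ŵ_k = Σ_j α_jk D_j / Σ_j α_jk A_j` at the current
baseline and β; Newton maximization (with step halving) of the profile
partial likelihood in β, a Cox partial likelihood with Breslow ties and
per-subject offsets `Σ_k α_jk ŵ_k`; and finally the weighted Breslow
baseline at the new β.  The (β, Λ0) pair is the joint conditional maximizer
of the expected complete-data objective given w, so the observable
log-likelihood never decreases (generalized EM); the test suite asserts
ascent with 1e−8 slack.

Numerical details:

* **Risk sets.** Subjects with observed time equal to an event time are at
  risk at that time (`time ≥ t` convention); ties among events are handled
  Breslow-style.
* **Newton termination.** The β maximizer stops at gradient ∞-norm < 1e−8,
  or takes one final full Newton step when the predicted gain drops below
  the floating-point resolution of the objective (|l| can be ~1e4–1e5, so
  gains < 1e−9 are not resolvable in double precision).  Estimates drifting
  past ‖β‖ > 10 trigger a monotone-likelihood warning (the classic
  no-events-in-one-level pathology).
* **Initialization.** Default: `n_restarts = 5` random hard assignments of
  groups to populations (distinct sub-seeds of `EMControl.seed`); mixture
  likelihoods are multimodal and restarts guard against local maxima.  An
  optional deterministic start (`init="na_quantile"`) splits groups into K
  quantile blocks of their Nelson–Aalen cumulative hazard at the median
  follow-up.  The best restart by final observable log-likelihood is kept.
* **Convergence.** Both the log-likelihood change (< 1e−6) *and* the max
  absolute change in (π, w, β) (< 1e−5) are required: the likelihood can
  plateau while (w, Λ0) still drift along the shared scale direction.
  `max_iter = 200` by default.
* **Degenerate populations.** If a population's posterior mass
  `Σ_j α_jk` falls below 1e−8 its w update is frozen and the fit is flagged
  degenerate rather than aborted; the empty-cluster selection rule consumes
  this flag.
* **w kept unconstrained during iteration** (no `w_1 = 1` constraint):
  conditional profiling keeps the pair (w, Λ0) identified at each step and
  converges more reliably; normalization to ratios is purely a reporting
  step.

## Standard errors

All three observed-information estimates operate on the free vector
`(π_1..π_{K−1}, w_1..w_K, β, λ_1..λ_M)` where `λ_m` are the baseline jumps:

* **exact** — analytic negative Hessian of the observable log-likelihood,
  assembled blockwise from per-group sufficient statistics;
* **louis** — per-group `E[B_j] − E[S_j S_jᵀ] + S*_j S*_jᵀ` with the
  expectation under the posterior α.  This decomposition is an algebraic
  identity for the observed information, so agreement with the exact
  assembly (machine precision in the tests) validates both derivations;
* **numeric** — central finite differences of the observable log-likelihood
  with one Richardson step, `(4·H_{h/2} − H_h)/3`, steps scaled to parameter
  magnitude (relative 1e−3) and halved near the feasibility boundary.  Cost
  is O(d²) likelihood evaluations, so requests beyond 500 free parameters
  are declined with a message — on large datasets use the exact or Louis
  method, which remain affordable.

The joint information has exactly one flat direction (the w/baseline scale).
Before inversion it is removed either by re-expressing the last baseline
jump through the fitted total cumulative baseline (default) or by fixing
`w_1`; gauge-invariant quantities (β, frailty ratios, π) have the same
standard errors under either constraint, which the tests verify.  Variances
of the reported ratios `w_k/w_1` use the second-order Taylor formula
`Var(ŵ_k/ŵ_1) = (μ_k/μ_1)²[σ²_1/μ²_1 + σ²_k/μ²_k − 2Cov/(μ_1μ_k)]`.
Baseline-jump variances are computed but not reported by default.  A
non-positive-definite constrained information falls back to a pseudo-inverse
with a rank-deficiency flag.

## Model selection and assignment

`fit_over_K` refits over a K grid and tabulates AIC/BIC with effective
parameter count `p + 2(K−1)` — (K−1) free proportions plus (K−1)
identifiable ratios; one w is absorbed by the baseline scale, and baseline
jumps are excluded as in Cox partial-likelihood practice (`param_count=
"full"` switches to `p + 2K − 1`).  The BIC sample size is the number of
groups J (the sampling unit of the latent structure; switchable to total
subjects).  `select_K` takes the argmin, ties to the smaller K.
`select_K_laird` iterates empty-cluster pruning: fit at `K_max`, count
populations with at least one argmax-assigned group and posterior mass
≥ 1e−8, refit at that count, repeat until stable (oscillations resolve to
the smaller K).  In line with its known behaviour, this rule tends to retain
more populations than BIC on weak-contrast data.  `assign_groups` labels
each group by argmax α and flags groups whose maximal membership is below
0.6 (configurable) as uncertain — these are the borderline providers worth
individual inspection.

## Simulator

`simulate_dataset` draws `z_j ~ Multinomial(π)`, covariates (default one
standard normal; Bernoulli and custom generators available), and event times
by inversion, `T* = Λ0⁻¹(−log U / (w_{z_j} e^{X'β}))` with
`Λ0⁻¹(s) = c·s^d` (defaults c = 0.01, d = 1.9, i.e.
`Λ0(t) = (100 t)^{1/1.9}`).  Default design: J = 100 groups of n_j = 50,
K = 2, β = 0.4, **no censoring** — the canonical conditions used by the
recovery studies; administrative and exponential censoring (rate solved to a
target censoring fraction) are available for sensitivity work, and a
rounding knob creates ties to exercise the Breslow tie handling.  Continuous
generation otherwise yields tie-free times.  Datasets are bit-reproducible
from the seed.

What the simulator does *not* emulate: covariate distributions of real
administrative data (mixed binary/count/age profiles), competing risks
(e.g. death versus readmission), group sizes varying over orders of
magnitude, and informative censoring.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation.

## Problem sizes used in the checks

Recovery and K-detection suites use the canonical design (J = 100,
n_j = 50, 50 replicates; BIC over K ∈ {1,2,3}).  The Wald-coverage suite
runs 200 replicates at J = 100, n_j = 10: coverage of β is a limiting
property that is already nominal at this size, and it keeps 200 exact
observed-information inversions (d ≈ 1000 free parameters each) affordable.
Information-matrix cross-validation uses J = 15, n_j = 8 so the numerical
Hessian (O(d²) evaluations) stays cheap.

## Known limitations

* Time-varying covariates, left truncation and interval censoring are out
  of scope; covariates are time-constant.
* The likelihood is multimodal in (π, w); restarts mitigate but cannot
  guarantee a global maximum — inspect `restart_logliks` for agreement.
* Very small populations (few groups, weak contrast) can produce boundary
  fits (π near 0) for which Wald standard errors are unreliable; such fits
  carry the degenerate flag.
* The numerical information method is intentionally size-limited; for large
  datasets the exact and Louis methods are the supported routes.
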