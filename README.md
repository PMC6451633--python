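# frailtymix

Cox proportional-hazards modelling of **hierarchical time-to-event data with
a non-parametric discrete shared frailty** — EM estimation, observed-information
standard errors, latent-population selection, and a matching simulator.

## The problem

In multilevel survival data — patients nested in healthcare providers,
animals in herds, subjects in centres — outcomes within a group are
correlated through unmeasured group-level characteristics.  The classical
remedy is a shared-frailty Cox model with a parametric (Gamma, log-Normal)
frailty distribution.  `frailtymix` instead gives the frailty a **discrete
distribution with K support points**, so that groups are probabilistically
*clustered* into latent populations of similar underlying risk, with no
parametric assumption on either the frailty or the baseline hazard.

Conditional on group *j* belonging to latent population *k*, subject *i* has
hazard

```
λ(t | X_ij, z_jk = 1) = λ0(t) · w_k · exp(X_ijᵀ β)
```

where `λ0` is a non-parametric baseline, `w_1..w_K > 0` are the frailty
support points with mixing proportions `π_1..π_K`, and `β` are log-hazard
ratios.  Only the ratios `w_k / min(w)` are identified (the scale is shared
with the baseline); they are the hazard ratios of each latent population
relative to the lowest-risk one.

Estimation is by a tailored EM algorithm: a closed-form E-step (Bayes
posterior membership α_jk), closed-form updates for π and w, a weighted
Breslow estimator for the cumulative baseline, and Newton maximization of a
profile partial likelihood for β (a Cox partial likelihood with offsets
`log Σ_k α_jk w_k`).  Standard errors come from the observed information
matrix by three routes — analytic (exact), the Louis EM decomposition, and
numerical differentiation — with delta-method variances for the frailty
ratios.  K is chosen by AIC/BIC over a grid or by an empty-cluster pruning
rule, and each group is assigned to `argmax_k α_jk`.

## Worked example

```python
import numpy as np
from frailtymix import (SimulationConfig, simulate_dataset, fit_em, EMControl,
                        se_report, fit_over_K, select_K)

cfg = SimulationConfig(J=100, n_j=50, K=2, pi=(0.3, 0.7), w=(1.0, 2.0),
                       beta=(0.4,), seed=42)
data, labels = simulate_dataset(cfg)          # 5000 subjects, 100 providers
fit = fit_em(data, K=2, control=EMControl(seed=1))
print(fit.params.pi, fit.frailty_ratios, fit.params.beta)
print(se_report(data, fit, method="louis").to_frame())
```

prints (labels relabeled so population 1 has the lowest frailty):

```
loglik = -42126.3  converged = True in 10 iterations
pi_hat = [0.306 0.694]
w2/w1  = 1.946
beta   = 0.379
parameter  estimate       se method
     pi_1  0.306378 0.046845  louis
    w2/w1  1.945919 0.063398  louis
  beta_x1  0.379238 0.014884  louis
correctly clustered groups: 98%
```

The fitted mixing proportions (0.31, 0.69), frailty ratio 1.95 and β̂ = 0.38
recover the generating truth (0.3, 0.7; 2.0; 0.4); the posterior membership
matrix `fit.alpha` assigns 98 % of groups to their true latent population.
Model selection over a K grid:

```
 K        loglik          AIC          BIC
 1 -42294.427118 84590.854236 84593.459406
 2 -42126.279203 84258.558406 84266.373916
 3 -42126.157389 84262.314778 84275.340629
BIC selects K = 2
```

The same workflow is available from the shell:

```sh
frailtymix simulate -o sim --J 100 --nj 50 --K 2 --w-ratio 2 --pi1 0.3 --seed 42
frailtymix fit sim/dataset.csv -o fit --K 2 --se louis
frailtymix fit sim/dataset.csv -o sel --K-grid 1:5 --criterion bic
```

`fit` writes `parameters.csv`, `alpha.csv`, `assignments.csv`,
`baseline.csv` and per-group Nelson–Aalen curves (`nelson_aalen.csv`,
long-format, colored by assigned population via the optional
`plot_nelson_aalen` helper).

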