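# jointmeta

One-stage meta-analysis of joint longitudinal and time-to-event individual
participant data (IPD).

Meta-analyses of trials that collected both a repeatedly measured biomarker
(e.g. systolic blood pressure) and a censored event outcome (e.g. time to
death) usually analyse the two outcomes separately. When the biomarker and
the hazard are associated — informative dropout, or a biomarker that drives
risk — the separate Cox analysis is biased: the treatment's log-hazard
effect is attenuated because the latent biomarker trajectory is an omitted
covariate. `jointmeta` fits the two outcomes *jointly* across all studies at
once, while accounting for between-study heterogeneity, and ships the
simulator and simulation-study harness used to characterise when each
modelling choice works.

## The model

For study *k*, subject *i*, measurement *j*:

```
Y_kij    = X1 β1 + Z2_kij b2_ki + Z3_ki b3_k + ε_kij          ε ~ N(0, σ_e²)
λ_ki(t)  = λ0(t) exp( X2 β2 + W2_ki(t) )
W2_ki(t) = α2 (b0_ki + b1_ki t) + α3 Z3_ki b3_k
```

with individual random intercept/slope `b2_ki ~ N(0, D)`, optional
study-level random effects `b3_k ~ N(0, A)`, and an unspecified (Breslow)
baseline hazard `λ0`. The shared zero-mean random effects link the
sub-models: `α2` is the individual-level association, `α3` the study-level
one. A subject's own event contribution evaluates `W2` at their survival
time `T_S`; inside risk sets the random slope is a latent time-varying
covariate.

Six **model groups** (0–5) differ only in how between-study heterogeneity
is handled: naive pooling (0); fixed study and treat-by-study terms in both
sub-models (1); fixed study main effects plus a shared study-level random
treatment effect (2); study-level random intercept + treatment effect only
(3); fixed longitudinal study terms with a study-stratified baseline hazard
(4); and a mixture of fixed terms, a random treatment effect and a
stratified hazard (5).

Fitting is by EM with the random effects as missing data. The E-step uses
pseudo-adaptive Gauss–Hermite quadrature (abscissae centred and scaled by
the conditional random-effect moments of an initial separate mixed-model
fit); the M-step combines closed-form longitudinal updates, a profiled
Breslow baseline and a damped Newton step for `(β2, α2, α3)`. Standard
errors come from the model-based information by default, or from a
within-study subject bootstrap (`jointmeta.bootstrap_se`) which is the
recommended source with a nonparametric baseline. Study-specific effects
(groups 1 and 4) are pooled by DerSimonian–Laird random-effects
meta-analysis.

## Worked example

```python
import numpy as np
from jointmeta import SimulationScenario, simulate_dataset, build_spec, fit_joint
from jointmeta.inference import pool_study_effects, study_treatment_effects

scenario = SimulationScenario(alpha2=0.5, alpha3=0.5)   # 5 studies x 500 subjects
dataset = simulate_dataset(scenario, seed=42)
print(f"event rate: {dataset.event_rate:.3f}")

result = fit_joint(dataset, build_spec(1))              # fixed-effects model group
print(f"converged: {result.converged} in {result.n_iter} EM iterations")
print(f"alpha2 (individual-level association): {result.alpha2:.3f}")

est, se = study_treatment_effects(
    result.beta2, result.cov_psi[:len(result.beta2), :len(result.beta2)],
    result.x2_names)
pooled = pool_study_effects(est, se)
print(f"pooled log-hazard treatment effect: {pooled.estimate:.3f} (SE {pooled.se:.3f})")
```

prints

```
event rate: 0.224
converged: True in 4 EM iterations
alpha2 (individual-level association): 0.536
pooled log-hazard treatment effect: 2.829 (SE 0.354)
```

The generating values were `alpha2 = 0.5` and a log-hazard treatment effect
of 3. The joint fit recovers both (up to one-replicate noise), while the
separate Cox analysis of the same dataset gives a pooled effect of 1.51 —
the attenuation that motivates joint modelling.

## Command line

```bash
jointmeta simulate --config set1_a2-0.5_a3-0.5 --seed 3 \
    --out-long long.csv --out-surv surv.csv --out-truth truth.csv
jointmeta fit --group 1 --long long.csv --surv surv.csv --out fit.json
jointmeta bootstrap --group 1 --long long.csv --surv surv.csv -B 100 --seed 7 --out se.json
jointmeta simstudy --set 1 --groups 0,1 --reps 100 --seed 11 --out results/
```

Scenario presets (`set1_*`, `set2_K-*`, `set3_A-*`) mirror the three
simulation sets: varying association strength, number of studies, and
between-study heterogeneity. CSV formats: longitudinal
`study,subject,time,y,treat`; survival `study,subject,survtime,status,treat`.

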