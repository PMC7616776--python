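# msmimpute

Multiple imputation of missing event times in an illness-death Markov
multi-state model, with the full simulation machinery needed to study how
imputation strategies behave when event times are missing at random — or
not.

## The problem

In clinical multi-state model (MSM) analyses the *states* a patient
passed through are often known while some of the *event times* are not.
The motivating setting is stem-cell transplantation: patients move from
transplant (state 0) to acute graft-versus-host disease (aGvHD, state 1)
and on to the composite absorbing state relapse/death (state 2), or
directly from transplant to relapse/death. Times of aGvHD onset are
missing for a substantial minority of patients, and the chance that a
time is missing depends on the event type. Complete-case analysis is
then biased, and maximum-likelihood interval-censoring methods fit
poorly when the censoring intervals are wide. Multiple imputation (MI)
of the missing times, followed by a standard MSM fit on each completed
dataset and Rubin's-rules pooling, is an attractive alternative — if the
imputation strategy respects the structure of the event history.

`msmimpute` implements and evaluates that workflow end to end:

* **Simulator** — cohorts from a three-state Markov illness-death model
  with Weibull proportional-hazards transition intensities
  α_ab(t) = (shape/scale)(t/scale)^(shape−1) exp(β_abᵀz) on the
  clock-forward (days since transplant) scale; defaults
  (shape, scale, β): 0→1 (1.5, 36, −0.8·z1), 0→2 (0.9, 120, 1.2·z1),
  1→2 (0.8, 160, 1.2·z1 − 1.0·z2), with z1 ~ Bern(0.2),
  z2 ~ Bern(0.45) and administrative censoring Uniform(365, 1825) days.
* **Missingness** — MCAR masking of 30% of time values, plus 11
  tabulated MAR/MNAR mechanisms (probabilistic rules in z2; deterministic
  thresholds at the 30th/70th empirical percentiles of the event-time
  distributions).
* **Imputation** — a fully-conditional-specification engine with type-1
  predictive mean matching (PMM; donors are observed cases with the
  nearest predicted mean, distance |θ*ᵀw_i − θ̂ᵀw_h|) and
  linear-regression draws, in four strategies: `PMM` (one model for
  everyone), `PMMSUBGP` (separate models for patients who did / did not
  experience aGvHD), `LINMI` (linear draws by subgroup), `PMMCOMP`
  (subgroup PMM on the first-event time and the aGvHD→relapse/death gap,
  which preserves event ordering by construction), plus a complete-case
  filter (`CCA`).
* **Model fitting** — Cox (Breslow ties, delayed entry, Breslow baseline
  increments) and left-truncated Weibull PH maximum likelihood per
  transition; a Markov-assumption test that adds the time of aGvHD, d,
  to the 1→2 model (true γ12 = 0 under the Markov DGM).
* **Estimands** — state occupation probabilities via the product
  integral P(s,t) = Π(I + dA(u)) (Aalen–Johansen from Cox fits; a fixed
  0.1-day grid for Weibull fits) and restricted expected length of stay
  RELOS e_b(t) = ∫₀ᵗ P_b(u) du with bootstrap (Cox) or delta-method
  (Weibull) standard errors.
* **Pooling & performance** — Rubin's rules with Barnard–Rubin degrees
  of freedom; bias, standardized bias, average model SE and coverage
  across simulation replicates.
* **Study runner / CLI** — the factorial study
  (scenario × method × model) with per-replicate reproducible seeding,
  and `msmimpute simulate | mask | impute | fit | estimate | run-study |
  report` subcommands for running the same workflow on your own CSVs.

## Worked example

```python
import numpy as np
from msmimpute import (
    DGMConfig, MIConfig, simulate_cohort, apply_scenario, fcs_impute,
    to_transition_datasets, fit_cox, markov_test, rubins_rules,
)

cohort = simulate_cohort(DGMConfig(n_patients=500, seed=7))
masked = apply_scenario(cohort, 9, seed=8)     # aGvHD MAR, smallest RD times MNAR
mi = fcs_impute(masked, MIConfig(method="PMMSUBGP", seed=9))

b_est, b_var, g_est, g_var = [], [], [], []
for completed in mi.datasets:
    fit = fit_cox(to_transition_datasets(completed, on_violation="drop")["12"])
    b_est.append(fit.beta[0]); b_var.append(fit.vcov[0, 0])
    mk = markov_test(completed, model="cox", on_violation="drop")
    g_est.append(mk.gamma); g_var.append(mk.se**2)
beta = rubins_rules(b_est, b_var, df_complete=495)
gamma = rubins_rules(g_est, g_var, df_complete=495)
print(f"beta_121 = {beta.estimate:.3f}  (95% CI {beta.ci[0]:.3f} to {beta.ci[1]:.3f})")
print(f"gamma_12 = {gamma.estimate:.4f}  (95% CI {gamma.ci[0]:.4f} to {gamma.ci[1]:.4f})")
```

prints

```
beta_121 = 1.097  (95% CI 0.656 to 1.539)
gamma_12 = -0.0058  (95% CI -0.0119 to 0.0003)
```

The pooled log hazard ratio for z1 in the aGvHD→relapse/death transition
(true value 1.2) lies well inside its interval, and the pooled
Markov-test coefficient for the time of aGvHD entry — a per-day effect
of −0.006 whose interval includes zero — gives no evidence that the
imputation manufactured a history effect (the data-generating model is
Markov, so the true value is 0).

The same pipeline from a shell:

```bash
msmimpute simulate --n 500 --seed 7 --out cohort.csv
msmimpute mask --cohort cohort.csv --scenario 9 --seed 8 --out masked.csv
msmimpute impute --cohort masked.csv --method PMMSUBGP --seed 9 --out imp/
msmimpute fit --cohort imp/imp1.csv --clip-violations --out fit.json
```

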