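# Methods

This note records the models, the default parameters and why they are
what they are, the numerical choices, and the places where the design
was genuinely open.

## The multi-state model and its data-generating mechanism

The process is a three-state illness-death model: transplant (0) →
aGvHD (1) → relapse/death (2), with a direct 0 → 2 path. All three
transitions run on the clock-forward time scale (days since transplant,
origin at transplant), so the 1 → 2 transition enters analysis with
delayed entry at the aGvHD time. The model is Markov: intensities depend
on the current state and time, not on the history of entry times.

Each transition intensity has Weibull proportional-hazards form
α_ab(t; z) = (shape/scale) (t/scale)^(shape−1) exp(β_abᵀz), i.e.
cumulative intensity A_ab(t; z) = (t/scale)^shape exp(β_abᵀz).
Defaults (the study conditions):

| transition | shape | scale (days) | coefficients |
|---|---|---|---|
| 0→1 | 1.5 | 36 | −0.8 · z1 |
| 0→2 | 0.9 | 120 | 1.2 · z1 |
| 1→2 | 0.8 | 160 | 1.2 · z1 − 1.0 · z2 |

with z1 ~ Bernoulli(0.2) (in relapse at transplant) and
z2 ~ Bernoulli(0.45) (double- vs single-cord transplant), independent.
Censoring is administrative, Uniform(365, 1825) days, independent of the
event process; the study description fixes only the one-to-five-year
window, and the continuous uniform is the natural non-informative choice
within it. Cohorts have 500 patients by default.

**Sampling construction.** The two cause-specific exit times from state
0 are drawn by inverting their cumulative intensities at independent
Exp(1) deviates and taking the earlier one; for cause-specific hazards
this is distributionally identical to drawing the exit time from the
total hazard and the destination from the relative intensities, and it
is closed-form here (no root finding on a sum of Weibull cumulative
hazards). A patient entering state 1 at t1 gets the 1→2 time by solving
A12(t2) − A12(t1) = Exp(1) on the same clock.

**Coding conventions.** A patient without aGvHD carries the
relapse/death (or censoring) time in the aGvHD-time column with
indicator 0; a censored patient carries the censoring time in both
columns with both indicators 0. Censored times are observed values —
never "missing". Ground-truth copies of the pre-masking times ride along
in `true_*` columns for performance evaluation only.

Two cohort-level facts matter downstream and are worth stating. First,
under these intensities state-0 occupancy at the minimum censoring time
(365 d) is numerically zero, so censored patients are (essentially)
always in the aGvHD state and the no-aGvHD subgroup contains no censored
records. Second, the complete-data distribution of relapse/death times
is extremely different on the two pathways (median ≈ 200 d via aGvHD,
≈ 14 d direct) — this asymmetry drives most of the interesting behaviour
of the missingness mechanisms and of stratified imputation. These
medians are properties of the complete (pre-censoring) event histories,
which `simulate_paths` exposes; the censoring-subjected observed-event
median on the aGvHD pathway is lower (≈ 167 d) because censoring
truncates the long right tail.

## Missingness mechanisms

MCAR masks exactly 30% of the 2n recorded time values — both columns,
all patients, censoring values included — drawn uniformly without
replacement. This is the only mechanism under which each patient is
complete with the same probability (0.49) regardless of pathway, which
is precisely the condition that makes complete-case analysis unbiased
here; restricting masking to experienced event times would make
completeness depend on the number of events and bias CCA even "at
random".

Scenarios 1–11 act on experienced event times only, via three rule
slots (aGvHD time; relapse/death without aGvHD; relapse/death after
aGvHD). MAR rules mask independently with probability 0.2(1 + z2)
(aGvHD) or 0.5(1 − 0.8 z2) (relapse/death); both average to ≈ 0.3 over
the z2 distribution. MNAR rules deterministically mask times strictly
below the 30th (or above the 70th) empirical percentile, recomputed
within each dataset; exact ties with the threshold are masked too. The
relapse/death percentile pools both pathways — which is why
"smallest-times" mechanisms hit mostly the direct pathway and
"largest-times" mechanisms mostly the aGvHD pathway. Mechanisms that
target one event type leave the other untouched, so ≈ 30% holds for the
targeted times, not over all event times.

For a no-aGvHD patient the two time columns are one underlying value, so
a scenario masking that event time blanks both columns; MCAR, which
operates per value, masks them independently.

## Imputation

All strategies run inside a fully-conditional-specification engine:
missing entries are initially filled by random draws from the observed
values of the variable (within the model's subgroup), then the
variable-wise models are updated in sweeps, each conditional on the
current completed data; values from the final sweep are kept. Five
sweeps by default, with the standard trace (per-iteration mean/SD of
imputed values) retained for convergence checks; when only one variable
is incomplete a single pass is exact and the engine stops there.
Defaults M = 5 imputations, donor pool 5 — the conventional software
defaults.

The regression step fits least squares of the target on intercept, z1,
z2, the other event time, and the relapse/death indicator (plus the
aGvHD indicator in the unstratified model), then draws
σ*² = RSS/χ²(n−q) and θ* ~ N(θ̂, σ*² (WᵀW)⁻¹) — the standard
approximate-Bayesian draw under a noninformative prior. Type-1 PMM
computes distances |θ*ᵀw_i − θ̂ᵀw_h| between the incomplete case
(posterior-drawn coefficients) and every observed case (point
estimates), admits the `donor_pool_size` nearest donors — ties at the
pool boundary included — and copies the response of one donor drawn
uniformly. Linear-regression imputation draws θ*ᵀw_i + σ*·N(0,1) and
floors negative times at 0.0001.

Strategy specifics:

* **PMM** — one model per variable over all patients.
* **PMMSUBGP / LINMI** — separate models for the aGvHD (δ1 = 1) and
  no-aGvHD (δ1 = 0) subgroups. In the no-aGvHD subgroup the other-event
  time is structurally identical to the response and is excluded; event
  indicators that are constant within a subgroup (always the aGvHD
  indicator; the relapse/death indicator too, since no censored patient
  sits in that subgroup) are dropped from that subgroup's model.
  Constant *covariates* still raise — that is a degenerate input, not a
  structural feature.
* **PMMCOMP** — subgroup PMM on the first-event time, plus the
  aGvHD→relapse/death gap for the aGvHD subgroup; relapse/death times
  are reconstructed post-imputation as aGvHD + gap wherever a component
  was imputed. Ordering holds by construction, at the price of
  discarding an observed relapse/death time when the aGvHD time is
  missing.
* **CCA** — drops every patient with a masked value (the software-NA
  default), no recovery attempted.

Deterministic mirror recovery: when masking blanks only one column of a
no-aGvHD patient, the value is known with certainty from the other
column and the engine restores it before any modelling. (A subgroup
regression on such rows is a perfect fit, so a chained-equations engine
converges to the same answer; doing it explicitly is cleaner.)

PMM and PMMSUBGP do not enforce the event ordering; imputed
relapse/death times occasionally precede the (observed or imputed) aGvHD
time, and these violations are counted on the `ImputedDatasets` object.
Donor pools tend to contain patients with the same event sequence, so
violations are rare except under mechanisms that remove the large
relapse/death times wholesale.

## Transition model fitting

`to_transition_datasets` expands a completed cohort into counting-process
rows: 0→1 (exit at the aGvHD time, status δ1), 0→2 (censored at aGvHD
for patients who transition to state 1), 1→2 (entry at the aGvHD time —
left truncation — restricted to δ1 = 1). A relapse/death time at or
before aGvHD is an ordering violation; the policy is `error` (default),
`drop` (exclude that patient's 1→2 row only — the record carries no
valid sojourn information; its 0→1 and 0→2 rows are kept), or `clip`
(push the time just past aGvHD). The study runner uses `drop` for
imputed data: clipping fabricates instantaneous transitions at extreme
values of the time-of-entry covariate and visibly biases the
Markov-test coefficient upward.

**Cox.** Newton–Raphson on the partial likelihood with Breslow tie
handling (imputed PMM values create genuine ties) and delayed-entry risk
sets {h : entry_h < t ≤ exit_h}; step-halving guarantees ascent;
convergence at a score below 1e−6 relative to the log likelihood;
monotone-likelihood drift (|β| > 50) is flagged, never silent. Breslow
baseline increments d_k / Σ_{R_k} exp(xᵀβ̂) are returned for the product
integral. Variances from the inverse observed information.

**Weibull PH.** Full likelihood in (log shape, log scale, β) with left
truncation entering through A(exit) − A(entry), maximised by BFGS with
the analytic gradient; a Nelder–Mead fallback plus up to three jittered
restarts handles rare line-search stalls. Standard errors from the
numeric observed information at the optimum; a fit with fewer than two
events, failed optimisation, or a non-positive-definite information
matrix is flagged non-converged. Within an MI ensemble, non-converged
fits are excluded from pooling with a logged count; a replicate loses
validity when more than half its imputations fail.

**Markov test.** The 1→2 model refitted with the time of aGvHD entry, d,
as an extra covariate: α12(t) = α120(t) exp(γ12 d + βᵀz). Under the
Markov DGM γ12 = 0, so the coverage of its Wald 95% CI measures whether
an imputation strategy fabricates history dependence. Wald intervals are
used throughout (the construction behind the reported coverages is not
otherwise pinned down).

## Estimands

State occupation probabilities come from the product integral
P(0,t) = Π (I + dA(u)) with α_aa = −Σ_b α_ab. From Cox fits the
increments are Breslow × exp(β̂ᵀz) and the grid is the pooled set of
event times (the covariate-conditional Aalen–Johansen path); a step
whose diagonal goes negative (an increment above one, possible in
bootstrap resamples with heavy ties) is reported via a warning and never
clipped silently. From Weibull fits the occupancy formulas
P0 = exp(−A01 − A02), P1 = ∫ P0 α01 exp(−(A12(t) − A12(u))) du are
evaluated on a fixed 0.1-day grid by a linear-time recursion with
trapezoidal increments (O(step²) error; the integrable singularity of a
shape-below-one intensity at t = 0 costs O(step^shape) in the first cell
only).

RELOS uses the left-endpoint step-function estimator
ê_b = Σ_m P̂_b(t_m)(t_{m+1} − t_m), last interval closed at the horizon
(730 days by default); the three states always sum to the horizon
exactly. Standard errors: nonparametric bootstrap over patients (B = 50;
B-insensitivity to within 25% against B = 300 is part of the test
suite) for Cox, and the delta method (central differences at relative
step 1e−5 against the block-diagonal parameter covariance) for Weibull.
RELOS confidence intervals are clipped to [0, horizon]. The covariate
pattern for study-level RELOS defaults to the reference profile
z = (0, 0) and is configurable; nothing in the evaluated performance
depends on this choice, which is why RELOS enters the acceptance layer
through its exact identities rather than a table lookup.

## Pooling and performance

Rubin's rules: Q̄ = mean, W̄ = mean within-variance, B = between-variance,
T = W̄ + (1 + 1/M)B, with Barnard–Rubin degrees of freedom when a
complete-data df is supplied (the study runner passes n − 5; at n = 500
the adjustment is minor but matches the default behaviour of standard
MI software). Between-variances below machine noise are snapped to zero
so the B = 0 ⇒ T = W̄ identity holds exactly. Performance per estimand ×
cell: bias, empirical SD, standardized bias (bias/SD), average model SE,
and coverage, each with Monte-Carlo standard errors; a zero SD with
nonzero bias yields an explicitly infinite standardized bias.

## Study runner and reproducibility

Replicate seeds are spawned from (master seed, replicate index), so any
single replicate can be rerun in isolation and results are independent
of execution order. Each replicate: simulate → mask → impute (or filter)
→ fit Cox and/or Weibull models and the Markov test per completed
dataset → pool → record. Failures are logged per replicate and never
abort a cell; a cell with more than 5% failed replicates is flagged.
The pipeline never reads the `true_*` columns downstream of masking
except in the performance evaluation.

Problem sizes: the package's own benchmark runs use 100k patients for
the data-generating summaries, 500 cohorts for masking calibration, 500
replicates for full-data parameter recovery, and 200–500 replicates at
M = 5 for the imputation study cells; the headline design (1000
replicates) is available by configuration. RELOS computation inside the
study runner is opt-in because its bootstrap SE dominates the cost of a
replicate.

## What the simulation does and does not establish

The generator matches the study conditions: Weibull PH intensities with
the stated parameters, binary covariates at the stated prevalences,
uniform administrative censoring, and mechanisms calibrated to ≈ 30%
missingness. It does not emulate several features of real transplant
registries: covariates are complete and binary (no missing or
categorical covariates, no auxiliary variables such as chronic-GvHD or
engraftment times), hazards are exactly proportional and exactly
Weibull, censoring is purely administrative, and the Markov assumption
holds by construction. Conclusions about method rankings under these
conditions — PMM variants nearly unbiased under MAR, stratification
helping the 1→2 parameters, linear-regression draws breaking event
ordering, CCA losing precision everywhere and validity outside MCAR —
are therefore statements about this model class, not about any
particular dataset.

Known limitations: the Weibull shape MLE carries the usual upward
small-sample bias (≈ +1% at a few hundred events), visible only as a
few-MCSE effect in very large replicate averages; coverage of the
Markov-test parameter under the largest-times-MNAR mechanism with a
Weibull model is reproduced in bias, SE and standardized bias but sits
a few points above the published coverage value, consistent with the
Monte-Carlo uncertainty of both runs; and the engine imputes event
times only — missing covariates or missing event indicators are out of
scope.
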