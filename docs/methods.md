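# Methods

This note documents the generative model behind the synthetic cohort, the
survival network and its losses, the benchmark Cox models, the evaluation
machinery, and the design choices made where several defensible options
existed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic longitudinal cohort

**What it emulates.** A pooled observational cohort in which each
participant has 1–4 exams inside an 8-year observation window preceding a
prediction (index) point, and is then followed for ASCVD events over a
10-year horizon with right censoring. The generator provides the three
statistical features the analysis question depends on: repeated correlated
measurements per person, between-person variation in risk-factor slopes,
and a hazard that depends on both the last measured levels and the slopes.

**Trajectories.** For the four lab factors (SBP, DBP, total cholesterol,
HDL), each person draws a baseline vector (their latent value at the index
point) from a multivariate normal with configurable means, SDs, and a 4×4
correlation matrix, plus an independent per-factor linear slope
(units/year). The recorded value at exam time `t ∈ [−8, 0]` is
`baseline + slope·t + noise`, with i.i.d. exam noise and clipping to
physiologic ranges (SBP 70–250 mmHg, DBP 40–150, TC 80–500, HDL 10–150
mg/dL) so downstream log transforms stay finite. A person-specific linear
trend is the minimum structure a slope-dependent hazard needs; no
within-person curvature or visit-triggered measurement is modelled. Exam
counts are drawn per participant from `schedule_mix`; the index exam sits at
`t = 0` and earlier exams are uniform over the window. Each factor is
missing at each exam with probability `missing_rate` (default 3%).

**Outcomes.** Conditional on the person, the event time is exponential with
rate `baseline_hazard · exp(lp)`, where `lp` is linear in (a) the *recorded*
last observed exam values, centred at the factor means, (b) the per-factor
slopes, and (c) the static covariates (age centred at 50, sex, race,
smoking, diabetes, treatment). Using the recorded rather than latent last
values makes the last exam a sufficient statistic when slope coefficients
are zero, which is what renders the dynamic-versus-cross-sectional
equivalence analysis well-posed. Censoring is an independent exponential
clock; times are truncated at the horizon with event = 0. The piecewise-
constant (exponential) form gives closed-form checks: with all coefficients
zero, the event fraction is `1 − exp(−h₀·10)`. The generator also writes a
`true_risk` diagnostic column (its own 10-year event probability per
person), which the calibration acceptance test scores against realized
outcomes.

**Default calibration.** The packaged defaults use the pooled-cohort
descriptive profile (factor means/SDs, 55% female, 27% Black, mean age
50.2) and `baseline_hazard = 0.0081`/person-year, chosen once so the default
configuration yields a ~13.9% ten-year event fraction at the reference
cohort size of 15,565 — the event rate the analysis is designed around. The
censoring rate (0.02/person-year) is a free parameter: the completeness of
follow-up in the motivating setting is not published, so the default is a
documented assumption, not an inference.

**Named study conditions.** Three additional configurations are frozen in
`dynrisk.config`: `slope_signal_config` (four exams each, SBP slope SD 2
mmHg/yr with log-hazard coefficient 0.3 per mmHg/yr next to a weak
last-value effect — the trajectory carries information the last exam lacks),
`last_value_config` (same geometry, slope coefficients zero — the last exam
carries everything), and `planted_sbp_config` (SBP level and slope the sole
hazard drivers; every other feature pure noise — used by the leave-one-out
importance analysis). These exist so signal-recovery claims are tested under
conditions where the truth is known by construction.

**What passing tests do not show.** The generator has linear trends,
exponential hazards, independent censoring, and missingness completely at
random. Real cohorts have none of these exactly; results here demonstrate
the machinery recovers known structure, not that the network improves
prediction in any particular real population.

## Eligibility

Participants are retained when strictly between 40 and 75 years old at the
prediction point, free of ASCVD during the observation window (the
`prior_ascvd` flag), and with at least one observed value of each of the
four labs. Exclusions are tallied per rule in that order (first rule
violated wins) and the filter is idempotent.

## The dynamic survival network

**Encoding.** Sequences are padded to length 4. Each step carries the
standardized lab values (training-set statistics only), a per-lab observed
mask, the time since the previous exam, and the broadcast statics. Missing
values are forward-filled within person; before the first observation the
training-set median is used. This mask + forward-fill + time-delta recipe is
the standard treatment for irregularly sampled clinical sequences; the
masks let the network distinguish measured from imputed values.

**Architecture.** One GRU layer (hidden 32 by default — the smallest size
adequate for ≤10 covariates and ≤4 steps), a linear step-ahead head
predicting the next exam's standardized labs from each hidden state,
single-layer additive attention (`score_t = v·tanh(W h_t + b)`) with masked
normalization so padded steps get exactly zero weight, and a fully
connected cause head (one hidden layer of 32, ReLU, optional dropout) over
`[context, last-exam covariates]` ending in a softmax of length
`n_bins + 1`. The output is a probability vector over 20 half-year bins
covering (0, 10] years plus a terminal event-free slot; the CIF at `t` sums
complete bins and interpolates linearly inside the containing bin. Half-year
bins balance temporal resolution against per-bin event counts at the cohort
sizes used here. The cross-sectional variant feeds only the last-exam
covariates to the cause head (`β` forced to 0, no encoder), so it is
invariant to all exams but the last by construction.

**Losses.** Likelihood: `−log p_k` for an event in bin `k`, `−log` of the
probability mass strictly after bin `k` for a censoring in bin `k` (so a
subject censored at the horizon with all mass on the terminal slot incurs
zero loss); probabilities floored at 1e−8. Ranking: mean of
`exp(−(F_i(s_i) − F_j(s_i))/σ)` over acceptable pairs (event `i` at `s_i`;
`j` with outcome time beyond `s_i`); zero when a batch has no pairs.
Step-ahead: MSE over observed next-exam values only; single-exam
participants contribute nothing. Defaults `α = β = 0.1`, `σ = 0.1`
(exposed in config with the grid {0.01, 0.1, 1} as the documented search
space); the composite loss is verified differentiable end-to-end by a
finite-difference gradient check at 1e−4 relative tolerance.

**Training.** Adam (lr 5e−3), batch 256, up to 60 epochs, early stopping on
the tuning-set composite loss with patience 5; the best-tuning-epoch
weights are returned. One experiment seed fans out via SHA-256-derived
sub-seeds (all < 2³¹) to the simulator, the split, weight initialization,
batch shuffling, and dropout, making runs bit-reproducible. Divergence
(non-finite loss) raises immediately. The network and training loop are
written against `autograd` (numpy-API reverse-mode differentiation), which
keeps every numerical choice visible in plain numpy.

## PCE benchmark

The published equation form is used: per race–sex stratum, a Cox model on
log-transformed covariates with
`risk = 1 − S₀(10)^exp(lp − mean_lp)`. Refitting uses lifelines'
`CoxPHFitter` on last-exam covariates; `S₀(10)` comes from the Breslow
cumulative baseline hazard and `mean_lp` is the training-sample mean linear
predictor (equal to the linear predictor at the covariate means, which is
the reference lifelines' baseline uses). Simulated event times are
continuous, so tie-handling conventions coincide. Strata need at least 25
events (configurable); the age-interaction term set is used only beyond
1,000 stratum events, because the interaction design is strongly collinear
at desk-scale sample sizes — below that the reduced main-effects term set is
fitted and recorded in the coefficient metadata. DBP is carried in the data
model but excluded from the default term list, matching the published
equation form; a switch adds an `ln_dbp` term. "Other" race scores with the
non-Black equations. The 2013 guideline coefficients are packaged as JSON
for fixed-coefficient scoring and are validated against the guideline's own
reference profile in the test suite; they are not used in any simulated
benchmark.

## Evaluation

**Labels.** Ten-year binary labels from censored outcomes: events by the
horizon are positives; subjects followed event-free to the horizon (time ≥
10, including exactly 10) are negatives; subjects censored earlier are
excluded. Exclusion is transparent but not unbiased for event *rates* under
censoring; an IPCW variant (Kaplan–Meier weights on the censoring
distribution) is available behind `policy="ipcw"` for sensitivity analysis.
The motivating analyses do not state their handling, so both are provided
and the simple policy is primary.

**Metrics.** AUROC via the rank/U-statistic identity (ties half-credit),
which equals brute-force pairwise concordance exactly — the enumeration
remains an independent oracle in the tests. Brier as the mean squared
score–label gap. Continuous NRI by sign counting, ties to neither
direction. Percentile bootstrap over participants (default B = 500, 95%),
seeded; a metric failing in >10% of resamples is an error, and degenerate
resamples otherwise count as failures rather than silently biasing the
interval. Decile calibration ranks by score with stable id tie-break (so
constant scores still give ten equal bins) and uses Wilson intervals for
the observed proportions. Subgroups (race–sex cells, age </≥ 60 with 60 in
the older group) report AUROC + CI, flagging under-powered groups as
non-estimable instead of dropping them. The 7.5% reclassification table
reports the four threshold cells plus the headline fractions (share of
reference-positives crossing down and the event-free share among them;
share of reference-negatives crossing up and the event share among them).

**Trajectory summaries.** Mean factor trajectories per risk-change group
(dynamic risk above/below PCE risk; exact ties counted separately) are
linear means over exam time fit under working independence with
cluster-robust (by participant) standard errors — the same point estimates
as a GEE with an independence working correlation; full non-independence
GEE machinery is out of scope. Groups with a single participant fall back
to the ordinary OLS covariance, the only estimable choice there.

**Feature importance.** Leave-one-out retraining: each removal drops the
feature jointly from the sequence channels (value + mask + step-ahead
target for labs) and the last-exam vector, retrains from scratch with the
same seed as the full model, and reports the test AUROC drop. Exactly
`k + 1` training runs for `k` features; hyperparameters are reused from the
full model rather than re-tuned per removal (a documented divergence risk).

## Pipeline

One run: simulate (or load CSVs) → eligibility → seeded 3:1:1
participant-level split (largest-remainder counts, unstratified simple
random sampling) → PCE fit on train + tune → both networks trained on train
with early stopping on tune → all models scored on the held-out test set
only → metrics, calibration, reclassification, optional importance and
trajectories, with every artifact, the fully resolved config, its hash, and
the per-stage seeds persisted to the output directory. No test-set row
influences any fitted parameter, standardization constant, or tuning
decision.

## Problem sizes

The default test suite and the acceptance script run at desk scale: the
signal-recovery comparison at n = 5,000 (five seeds), the importance
analysis at n = 3,000, the calibration check at n = 10,000, Cox recovery at
n = 10,000, and the end-to-end pipeline at n = 6,000, with the event-rate
quantity computed at the reference size 15,565. These sizes are the
package's default experiment scale; all are configurable upward.

## Known limitations

- The generator's linearity, exponential hazards, and MCAR missingness are
  idealizations; see above for what passing tests do and do not show.
- Single-cause formulation: non-CVD death is treated as censoring, so no
  competing-risks cause dimension exists.
- The binary-label exclusion policy conditions on follow-up; IPCW is
  provided but not the primary path.
- No GPU path and no hyperparameter search beyond the documented grid; the
  architecture is deliberately small.
- Attention weights are exposed for inspection but no interpretability
  claims are made from them.
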