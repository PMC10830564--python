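# dynrisk

Dynamic deep-learning prediction of 10-year atherosclerotic cardiovascular
disease (ASCVD) risk from longitudinal risk-factor histories, benchmarked
against Pooled-Cohort-Equation-form (PCE) Cox models.

## Who this is for

Biostatisticians and epidemiologists who want to study whether repeated
risk-factor measurements (blood pressure, cholesterol) improve 10-year ASCVD
risk prediction over a single cross-sectional assessment. Real pooled-cohort
data of this kind is typically unavailable for reuse, so the package ships a
synthetic longitudinal cohort generator with the statistical structure the
question requires — correlated person-specific risk-factor trajectories,
trajectory-dependent hazards, and right censoring — and a complete,
seeded analysis pipeline over it.

## The models

**Dynamic discrete-time survival network.** Each participant contributes 1–4
exams inside an 8-year observation window (SBP, DBP, total cholesterol, HDL,
with missingness masks and inter-exam time gaps) plus static covariates
(age, sex, race, smoking, diabetes, hypertension treatment). A shared GRU
encoder processes the sequence and also predicts the next exam's lab values;
masked additive attention pools the hidden states into a context vector; a
fully connected cause head maps context + last-exam covariates through a
softmax over 20 half-year time bins plus one terminal event-free slot. The
10-year risk is the cumulative incidence F(10) = 1 − (terminal mass).
Training minimizes

```
L = L_likelihood + α · L_ranking + β · L_prediction
```

where `L_likelihood` is the discrete-time negative log-likelihood (event mass
at the event bin; survival mass past the censoring bin), `L_ranking` averages
the kernel `exp(−(F_i(s_i) − F_j(s_i))/σ)` over pairs where subject *i* has an
event at `s_i` and subject *j* is still at risk, and `L_prediction` is the MSE
of the step-ahead covariate predictions on observed values. A
**cross-sectional variant** feeds only the last exam to the cause head,
isolating the value of the longitudinal history.

**PCE benchmark.** Race- and sex-stratified Cox proportional-hazards models
in the published equation form `risk = 1 − S₀(10)^exp(lp − mean_lp)` with
log-transformed covariates, refit on the training sample (the published 2013
guideline coefficients are also packaged for fixed-coefficient scoring).

Evaluation covers censoring-aware AUROC with bootstrap CIs, Brier score,
continuous net reclassification improvement (NRI), decile calibration,
race/sex/age subgroup discrimination, 7.5%-threshold reclassification
bookkeeping, leave-one-out retraining feature importance, and risk-change
group trajectory summaries (cluster-robust linear trends).

## Worked example

```bash
dynrisk run --seed 5 --n 3000 --out scratch/demo
```

runs simulate → eligibility → 3:1:1 split → PCE fit (train+tune) → dynamic
and cross-sectional training (train, early-stopped on tune) → evaluation on
the held-out test set, and logs:

```
INFO pce: AUROC 0.730 Brier 0.1073
INFO cross_sectional: AUROC 0.703 Brier 0.1066
INFO dynamic: AUROC 0.733 Brier 0.1047
```

AUROC is the probability that a random event outranks a random non-event
(0.5 = chance); Brier is the mean squared gap between predicted risk and the
10-year outcome (lower is better). `scratch/demo/` then contains the cohort
CSVs, split assignment, per-model `risks_*.csv`, decile calibration tables,
the 7.5%-threshold reclassification table, and `report.json`/`report.md`
with bootstrap CIs and subgroup AUROCs. The same steps are available as
library calls (`dynrisk.run_experiment`) and as individual subcommands
(`simulate`, `split`, `train`, `predict`, `evaluate`, `importance`,
`trajectories`).

Python API sketch:

```python
from dynrisk import RunConfig, run_experiment, default_simulation_config

cfg = RunConfig(simulation=default_simulation_config(n_participants=5000), seed=5)
report = run_experiment(cfg, "scratch/demo")
print(report["models"]["dynamic"]["auroc"])
```

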