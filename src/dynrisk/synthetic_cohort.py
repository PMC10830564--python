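"""Synthetic longitudinal cohort generator and eligibility filtering.

The generator emulates the statistical structure a dynamic ASCVD risk
model is trained on: each participant has 1-4 exams inside an 8-year
observation window, the four lab factors (SBP, DBP, total cholesterol,
HDL) follow person-specific linear trajectories (random intercept +
random slope) with correlated baselines and i.i.d. exam noise, and the
time to ASCVD after the prediction point follows an exponential
(piecewise-constant hazard) model whose log-hazard is linear in the
last-exam factor levels, the per-factor slopes, and the static
covariates.  Censoring is an independent exponential clock; follow-up
is truncated at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FACTORS, PHYSIOLOGIC_RANGES, SimulationConfig

STATIC_COLUMNS = [
    "id",
    "sex",
    "race",
    "age_at_prediction",
    "smoker",
    "diabetes",
    "htn_treatment",
    "prior_ascvd",
]
EXAM_COLUMNS = ["id", "exam_time_years"] + list(FACTORS) + [f"{f}_observed" for f in FACTORS]
OUTCOME_COLUMNS = ["id", "time_years", "event"]


@dataclass
class CohortDataset:
    """Aligned static, exam, and outcome tables for one cohort.

    ``statics`` has one row per participant; ``exams`` is long-format
    (one row per exam) with per-factor observed flags and NaN for
    missing measurements; ``outcomes`` holds time from the prediction
    point to event or censoring in years plus the event indicator.
    """

    statics: pd.DataFrame
    exams: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = set(self.statics["id"])
        if set(self.outcomes["id"]) != ids or set(self.exams["id"]) - ids:
            raise ValueError("participant ids do not align across tables")

    @property
    def n(self) -> int:
        return len(self.statics)

    @property
    def ids(self) -> np.ndarray:
        return self.statics["id"].to_numpy()

    def subset(self, ids) -> "CohortDataset":
        keep = pd.Index(ids)
        return CohortDataset(
            statics=self.statics[self.statics["id"].isin(keep)].reset_index(drop=True),
            exams=self.exams[self.exams["id"].isin(keep)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["id"].isin(keep)].reset_index(drop=True),
        )

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.statics.to_csv(directory / "static.csv", index=False)
        self.exams.to_csv(directory / "exams.csv", index=False)
        self.outcomes.to_csv(directory / "outcomes.csv", index=False)

    @classmethod
    def from_csv(cls, directory) -> "CohortDataset":
        directory = Path(directory)
        statics = pd.read_csv(directory / "static.csv")
        exams = pd.read_csv(directory / "exams.csv")
        outcomes = pd.read_csv(directory / "outcomes.csv")
        for col in ("smoker", "diabetes", "htn_treatment", "prior_ascvd"):
            if col in statics:
                statics[col] = statics[col].astype(bool)
        for f in FACTORS:
            exams[f"{f}_observed"] = exams[f"{f}_observed"].astype(bool)
        return cls(statics=statics, exams=exams, outcomes=outcomes)

    def equals(self, other: "CohortDataset") -> bool:
        return (
            self.statics.equals(other.statics)
            and self.exams.equals(other.exams)
            and self.outcomes.equals(other.outcomes)
        )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw a full synthetic cohort from the generative model.

    Reproducible: the same config (including seed) yields an identical
    dataset.  Event times are exponential conditional on the linear
    predictor; censoring is an independent exponential clock; times are
    truncated at the horizon with event = 0.
    """
    config.validate()
    if config.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    k_factors = len(FACTORS)

    ids = np.arange(n)
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n), *config.age_bounds
    )
    female = rng.random(n) < config.p_female
    black = rng.random(n) < config.p_black
    smoker = rng.random(n) < config.p_smoker
    diabetes = rng.random(n) < config.p_diabetes
    treated = rng.random(n) < config.p_htn_treatment
    prior = rng.random(n) < config.p_prior_ascvd

    # person-level factor baselines (value at the prediction point) and slopes
    sds = np.array([config.factor_sds[f] for f in FACTORS])
    means = np.array([config.factor_means[f] for f in FACTORS])
    corr = np.asarray(config.factor_correlation, dtype=float)
    cov = np.outer(sds, sds) * corr
    base = rng.multivariate_normal(means, cov, size=n, method="cholesky")
    slope_sds = np.array([config.slope_sds[f] for f in FACTORS])
    slopes = rng.normal(0.0, 1.0, size=(n, k_factors)) * slope_sds

    # exam schedules: the index exam is at t = 0; earlier exams uniform in the window
    counts = np.array(sorted(config.schedule_mix))
    probs = np.array([config.schedule_mix[k] for k in counts])
    n_exams = rng.choice(counts, size=n, p=probs)

    exam_rows = []
    noise_sds = np.array([config.noise_sds[f] for f in FACTORS])
    # the hazard acts on the recorded (noisy, clipped) last observed values;
    # falls back to the latent value when a factor is never observed
    last_recorded = base.copy()
    for i in range(n):
        k = int(n_exams[i])
        earlier = np.sort(rng.uniform(-config.observation_window, -0.5, size=k - 1))
        times = np.concatenate([earlier, [0.0]])
        latent = base[i][None, :] + slopes[i][None, :] * times[:, None]
        noisy = latent + rng.normal(0.0, 1.0, size=(k, k_factors)) * noise_sds
        for j, f in enumerate(FACTORS):
            lo, hi = PHYSIOLOGIC_RANGES[f]
            noisy[:, j] = np.clip(noisy[:, j], lo, hi)
        observed = rng.random((k, k_factors)) >= config.missing_rate
        values = np.where(observed, noisy, np.nan)
        for j in range(k_factors):
            col = values[:, j]
            if np.isfinite(col).any():
                last_recorded[i, j] = col[np.isfinite(col)][-1]
        for t_idx in range(k):
            exam_rows.append(
                (ids[i], times[t_idx], *values[t_idx], *observed[t_idx])
            )

    exams = pd.DataFrame(exam_rows, columns=EXAM_COLUMNS)
    for f in FACTORS:
        exams[f"{f}_observed"] = exams[f"{f}_observed"].astype(bool)
    exams["id"] = exams["id"].astype(int)

    # hazard on centred last values, slopes and statics
    hc = config.hazard_coefs
    lp = np.zeros(n)
    for j, f in enumerate(FACTORS):
        lp += hc["last"].get(f, 0.0) * (last_recorded[:, j] - means[j])
        lp += hc["slope"].get(f, 0.0) * slopes[:, j]
    static_vals = {
        "age": age - config.age_center,
        "male": (~female).astype(float),
        "black": black.astype(float),
        "smoker": smoker.astype(float),
        "diabetes": diabetes.astype(float),
        "htn_treatment": treated.astype(float),
    }
    for name, coef in hc.get("static", {}).items():
        lp += coef * static_vals[name]

    lam = config.baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        t_event = np.where(lam > 0, rng.exponential(1.0, size=n) / np.maximum(lam, 1e-300), np.inf)
        if config.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
    time = np.minimum.reduce([t_event, t_cens, np.full(n, config.horizon)])
    event = (t_event <= t_cens) & (t_event <= config.horizon)
    time = np.maximum(time, 1e-6)

    statics = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(female, "female", "male"),
            "race": np.where(black, "black", "other"),
            "age_at_prediction": age,
            "smoker": smoker,
            "diabetes": diabetes,
            "htn_treatment": treated,
            "prior_ascvd": prior,
        }
    )
    # diagnostic: the generator's own 10-year event probability per person
    true_risk = 1.0 - np.exp(-lam * config.horizon)
    outcomes = pd.DataFrame(
        {"id": ids, "time_years": time, "event": event.astype(int), "true_risk": true_risk}
    )
    return CohortDataset(statics=statics, exams=exams, outcomes=outcomes)


def apply_eligibility(cohort: CohortDataset) -> tuple[CohortDataset, dict[str, int]]:
    """Apply the analytic-sample eligibility rules.

    Retains participants aged strictly between 40 and 75 at the
    prediction point, with no ASCVD during the observation window, and
    with at least one observed measurement of each of SBP, DBP, total
    cholesterol and HDL.  Returns the filtered cohort plus per-rule
    exclusion tallies (each excluded participant counted once, against
    the first rule violated, in the order age, prior event, labs).
    Idempotent.
    """
    s = cohort.statics
    age_ok = (s["age_at_prediction"] > 40) & (s["age_at_prediction"] < 75)
    prior_ok = ~s["prior_ascvd"].astype(bool) if "prior_ascvd" in s else pd.Series(True, index=s.index)

    obs = cohort.exams.groupby("id")[[f"{f}_observed" for f in FACTORS]].any()
    labs_ok_map = obs.all(axis=1)
    labs_ok = s["id"].map(labs_ok_map).fillna(False).astype(bool)

    tallies = {
        "age": int((~age_ok).sum()),
        "prior_event": int((age_ok & ~prior_ok).sum()),
        "labs": int((age_ok & prior_ok & ~labs_ok).sum()),
    }
    keep = s.loc[age_ok & prior_ok & labs_ok, "id"]
    if keep.empty:
        import warnings

        warnings.warn("no participants remain after eligibility filtering")
    return cohort.subset(keep), tallies


def event_fraction(cohort: CohortDataset) -> float:
    """Fraction of participants with an observed event by the horizon."""
    return float(cohort.outcomes["event"].mean())
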