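"""Pooled-Cohort-Equation-form 10-year ASCVD risk models.

The PCE are race- and sex-stratified Cox proportional-hazards risk
equations: within each stratum the 10-year risk is

    risk = 1 - S0(10) ** exp(lp - mean_lp)

where ``lp`` is a linear predictor over log-transformed continuous
covariates (with age interactions), ``mean_lp`` the stratum mean of
the linear predictor in the fitting sample, and ``S0(10)`` the
baseline survival at 10 years.  Two modes are supported: refitting the
equations on a training cohort (Cox partial likelihood via lifelines,
Breslow baseline hazard), and scoring with the published 2013
guideline coefficients shipped as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .config import FACTORS
from .synthetic_cohort import CohortDataset

STRATA = ("black-female", "black-male", "other-female", "other-male")

#: published-form PCE term set (the non-Black female stratum uses all of
#: these; other strata use subsets, which is handled by zero coefficients)
FULL_TERMS = (
    "ln_age",
    "ln_age_sq",
    "ln_tc",
    "ln_age_x_ln_tc",
    "ln_hdl",
    "ln_age_x_ln_hdl",
    "ln_sbp_treated",
    "ln_age_x_ln_sbp_treated",
    "ln_sbp_untreated",
    "ln_age_x_ln_sbp_untreated",
    "smoker",
    "ln_age_x_smoker",
    "diabetes",
)

#: reduced term set used when a stratum has too few events for interactions
REDUCED_TERMS = (
    "ln_age",
    "ln_tc",
    "ln_hdl",
    "ln_sbp_treated",
    "ln_sbp_untreated",
    "smoker",
    "diabetes",
)


class FitError(RuntimeError):
    """Cox model failed to converge or showed separation."""


@dataclass
class RiskProfile:
    """A single participant's covariates at the prediction point."""

    age: float
    sex: str  # "male" | "female"
    race: str  # "black" | "other"
    sbp: float
    treated: bool
    total_chol: float
    hdl: float
    smoker: bool
    diabetes: bool
    dbp: float | None = None

    @property
    def stratum(self) -> str:
        race = "black" if self.race == "black" else "other"
        return f"{race}-{self.sex}"


@dataclass
class PCECoefficients:
    stratum: str
    terms: dict[str, float]
    mean_lp: float
    baseline_survival_10y: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival_10y <= 1.0:
            raise ValueError("baseline_survival_10y must be in (0, 1]")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term names must be unique")


def stratum_of(sex: str, race: str) -> str:
    return f"{'black' if race == 'black' else 'other'}-{sex}"


def _check_positive(profile: RiskProfile) -> None:
    for name, value in (
        ("age", profile.age),
        ("sbp", profile.sbp),
        ("total_chol", profile.total_chol),
        ("hdl", profile.hdl),
    ):
        if not value > 0:
            raise ValueError(f"covariate {name!r} must be positive for log transform, got {value}")


def compute_terms(profile: RiskProfile) -> dict[str, float]:
    """Transformed covariate values for every published-form term."""
    _check_positive(profile)
    la = np.log(profile.age)
    lt = np.log(profile.total_chol)
    lh = np.log(profile.hdl)
    ls = np.log(profile.sbp)
    treated = bool(profile.treated)
    smoker = float(profile.smoker)
    out = {
        "ln_age": la,
        "ln_age_sq": la**2,
        "ln_tc": lt,
        "ln_age_x_ln_tc": la * lt,
        "ln_hdl": lh,
        "ln_age_x_ln_hdl": la * lh,
        "ln_sbp_treated": ls if treated else 0.0,
        "ln_age_x_ln_sbp_treated": la * ls if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else ls,
        "ln_age_x_ln_sbp_untreated": 0.0 if treated else la * ls,
        "smoker": smoker,
        "ln_age_x_smoker": la * smoker,
        "diabetes": float(profile.diabetes),
    }
    if profile.dbp is not None:
        if not profile.dbp > 0:
            raise ValueError("covariate 'dbp' must be positive for log transform")
        out["ln_dbp"] = np.log(profile.dbp)
    return out


def pce_linear_predictor(profile: RiskProfile, coeffs: PCECoefficients) -> float:
    """Sum of coefficient x transformed covariate over the term set."""
    terms = compute_terms(profile)
    lp = 0.0
    for name, beta in coeffs.terms.items():
        if name not in terms:
            raise KeyError(f"unknown PCE term {name!r}")
        lp += beta * terms[name]
    return float(lp)


def pce_ten_year_risk(profile: RiskProfile, coeffs: PCECoefficients) -> float:
    lp = pce_linear_predictor(profile, coeffs)
    risk = 1.0 - coeffs.baseline_survival_10y ** np.exp(lp - coeffs.mean_lp)
    return float(np.clip(risk, 0.0, 1.0))


RISK_CATEGORIES = ("low", "borderline", "intermediate", "high")


def classify_risk(risk: float) -> str:
    """Guideline risk category: low < 5% <= borderline < 7.5% <= intermediate < 20% <= high.

    Boundaries are closed on the left of the higher category.
    """
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must be in [0, 1], got {risk}")
    if risk < 0.05:
        return "low"
    if risk < 0.075:
        return "borderline"
    if risk < 0.20:
        return "intermediate"
    return "high"


# ---------------------------------------------------------------------------
# data preparation


def last_exam_frame(cohort: CohortDataset) -> pd.DataFrame:
    """One row per participant: statics plus last observed value of each factor."""
    exams = cohort.exams.sort_values(["id", "exam_time_years"])
    cols = {}
    for f in FACTORS:
        obs = exams[exams[f"{f}_observed"]]
        cols[f] = obs.groupby("id")[f].last()
    wide = pd.DataFrame(cols)
    out = cohort.statics.merge(wide, left_on="id", right_index=True, how="left")
    return out


def _terms_frame(df: pd.DataFrame, term_names, include_dbp: bool = False) -> pd.DataFrame:
    """Vectorised published-form transforms for a last-exam frame."""
    for col in ("age_at_prediction", "sbp", "tc", "hdl"):
        bad = ~(df[col] > 0)
        if bad.any():
            raise ValueError(f"covariate {col!r} must be positive for log transform")
    la = np.log(df["age_at_prediction"].to_numpy(float))
    lt = np.log(df["tc"].to_numpy(float))
    lh = np.log(df["hdl"].to_numpy(float))
    ls = np.log(df["sbp"].to_numpy(float))
    treated = df["htn_treatment"].to_numpy(bool)
    smoker = df["smoker"].to_numpy(bool).astype(float)
    diabetes = df["diabetes"].to_numpy(bool).astype(float)
    all_terms = {
        "ln_age": la,
        "ln_age_sq": la**2,
        "ln_tc": lt,
        "ln_age_x_ln_tc": la * lt,
        "ln_hdl": lh,
        "ln_age_x_ln_hdl": la * lh,
        "ln_sbp_treated": np.where(treated, ls, 0.0),
        "ln_age_x_ln_sbp_treated": np.where(treated, la * ls, 0.0),
        "ln_sbp_untreated": np.where(treated, 0.0, ls),
        "ln_age_x_ln_sbp_untreated": np.where(treated, 0.0, la * ls),
        "smoker": smoker,
        "ln_age_x_smoker": la * smoker,
        "diabetes": diabetes,
    }
    if include_dbp:
        all_terms["ln_dbp"] = np.log(df["dbp"].to_numpy(float))
    return pd.DataFrame({t: all_terms[t] for t in term_names}, index=df.index)


# ---------------------------------------------------------------------------
# fitting


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    max_coef: float = 50.0,
) -> CoxPHFitter:
    """Cox PH fit on a prepared frame; raises FitError on non-convergence
    or separation (any |coefficient| beyond ``max_coef``)."""
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        cph.fit(df[[duration_col, event_col] + covariates], duration_col=duration_col,
                event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise FitError(f"Cox fit failed: {exc}") from exc
    if (cph.params_.abs() > max_coef).any():
        raise FitError(f"separation suspected: |coef| > {max_coef}")
    return cph

def _baseline_survival_at(cph: CoxPHFitter, t: float) -> float:
    bs = cph.baseline_survival_
    idx = bs.index.to_numpy(float)
    vals = bs.iloc[:, 0].to_numpy(float)
    mask = idx <= t
    return float(vals[mask][-1]) if mask.any() else 1.0


def fit_pce_cox(
    train: CohortDataset,
    term_spec: tuple[str, ...] | None = None,
    min_events: int = 25,
    interaction_min_events: int = 1000,
    include_dbp: bool = False,
    horizon: float = 10.0,
) -> dict[str, PCECoefficients]:
    """Refit PCE-form Cox models per race-sex stratum on last-exam covariates.

    A stratum uses the full interaction term set when its event count
    exceeds ``interaction_min_events``, otherwise the reduced set.
    S0(horizon) comes from the Breslow cumulative baseline hazard;
    mean_lp is the training-set mean linear predictor.
    """
    frame = last_exam_frame(train).merge(train.outcomes, on="id")
    frame = frame.dropna(subset=list(FACTORS))
    out: dict[str, PCECoefficients] = {}
    for stratum in STRATA:
        race, sex = stratum.split("-")
        sub = frame[(frame["sex"] == sex) & ((frame["race"] == "black") == (race == "black"))]
        n_events = int(sub["event"].sum())
        if n_events < min_events:
            raise FitError(
                f"stratum {stratum}: {n_events} events < required minimum {min_events}"
            )
        if term_spec is not None:
            terms = tuple(term_spec)
        else:
            terms = FULL_TERMS if n_events > interaction_min_events else REDUCED_TERMS
        if include_dbp:
            terms = terms + ("ln_dbp",)
        X = _terms_frame(sub, terms, include_dbp=include_dbp)
        # drop constant columns (e.g. no treated subjects in a stratum)
        keep = [c for c in X.columns if X[c].nunique() > 1]
        data = X[keep].copy()
        data["time_years"] = sub["time_years"].to_numpy()
        data["event"] = sub["event"].to_numpy()
        cph = fit_cox(data, "time_years", "event", keep)
        coefs = {c: float(cph.params_[c]) for c in keep}
        lp = X[keep].to_numpy() @ np.array([coefs[c] for c in keep])
        out[stratum] = PCECoefficients(
            stratum=stratum,
            terms=coefs,
            mean_lp=float(lp.mean()),
            baseline_survival_10y=_baseline_survival_at(cph, horizon),
            meta={"n": int(len(sub)), "n_events": n_events, "term_set":
                  "full" if terms is FULL_TERMS else "custom/reduced"},
        )
    return out


def score_cohort(cohort: CohortDataset, coeffs: dict[str, PCECoefficients]) -> pd.DataFrame:
    """Ten-year PCE risk for every participant with complete last-exam labs."""
    frame = last_exam_frame(cohort)
    frame = frame.dropna(subset=list(FACTORS))
    risks = np.empty(len(frame))
    for stratum, co in coeffs.items():
        race, sex = stratum.split("-")
        mask = ((frame["sex"] == sex) & ((frame["race"] == "black") == (race == "black"))).to_numpy()
        if not mask.any():
            continue
        sub = frame[mask]
        X = _terms_frame(sub, list(co.terms), include_dbp="ln_dbp" in co.terms)
        lp = X.to_numpy() @ np.array(list(co.terms.values()))
        risks[mask] = np.clip(1.0 - co.baseline_survival_10y ** np.exp(lp - co.mean_lp), 0, 1)
    return pd.DataFrame({"id": frame["id"].to_numpy(), "risk_10y": risks})


# ---------------------------------------------------------------------------
# serialization


def save_coefficients(coeffs: dict[str, PCECoefficients], path) -> None:
    payload = {
        s: {
            "terms": c.terms,
            "mean_lp": c.mean_lp,
            "baseline_survival_10y": c.baseline_survival_10y,
            "meta": c.meta,
        }
        for s, c in coeffs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_coefficients(path) -> dict[str, PCECoefficients]:
    payload = json.loads(Path(path).read_text())
    return {
        s: PCECoefficients(
            stratum=s,
            terms=d["terms"],
            mean_lp=d["mean_lp"],
            baseline_survival_10y=d["baseline_survival_10y"],
            meta=d.get("meta", {}),
        )
        for s, d in payload.items()
    }


def published_2013_coefficients() -> dict[str, PCECoefficients]:
    """The 2013 ACC/AHA guideline coefficient sets (fixed-coefficient mode).

    Used for cross-checks against public risk calculators; refitting on a
    training cohort is the primary mode.
    """
    path = resources.files("dynrisk.data") / "pce_2013.json"
    with resources.as_file(path) as p:
        return load_coefficients(p)
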