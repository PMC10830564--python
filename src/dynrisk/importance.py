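"""Leave-one-out feature importance and risk-change trajectory summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .deep_survival import ALL_FEATURES, SurvivalNetConfig, train
from .evaluation import auroc, binary_labels_at_horizon, bootstrap_ci
from .synthetic_cohort import CohortDataset


def _test_auroc(model, test: CohortDataset, horizon: float, B: int, seed: int):
    risks = model.predict_risk_frame(test, "model")
    labels = binary_labels_at_horizon(test.outcomes, horizon=horizon)
    merged = risks.merge(labels[labels["included"]], on="id")
    scored = pd.DataFrame({"score": merged["risk_10y"], "label": merged["label"]})
    return bootstrap_ci(lambda d: auroc(d["score"], d["label"]), scored, B=B, seed=seed)


def loo_importance(
    config: SurvivalNetConfig,
    train_cohort: CohortDataset,
    tune_cohort: CohortDataset,
    test_cohort: CohortDataset,
    features: list[str] | None = None,
    B: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Retrain-and-retest importance: one full training run per removed feature.

    Removing a longitudinal lab drops its value, mask, and step-ahead
    target jointly; removing a static drops it from the sequence
    broadcast and the last-exam vector.  The same training seed is used
    for every run so runs differ only in the removed feature.  Rows are
    sorted by AUROC drop (descending); the full-model row has delta 0.
    """
    features = list(ALL_FEATURES) if features is None else features
    unknown = set(features) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    seed = config.seed if seed is None else seed

    import dataclasses

    cfg = dataclasses.replace(config, seed=seed)
    full_model = train(cfg, train_cohort, tune_cohort)
    lo, full_auc, hi = _test_auroc(full_model, test_cohort, cfg.horizon, B, seed)
    rows = [
        {"feature": "<full model>", "auroc": full_auc, "ci_lo": lo, "ci_hi": hi, "delta": 0.0}
    ]
    for feat in features:
        model = train(cfg, train_cohort, tune_cohort, exclude={feat})
        lo, auc, hi = _test_auroc(model, test_cohort, cfg.horizon, B, seed)
        rows.append(
            {"feature": feat, "auroc": auc, "ci_lo": lo, "ci_hi": hi, "delta": full_auc - auc}
        )
    out = pd.DataFrame(rows)
    return pd.concat(
        [out.iloc[:1], out.iloc[1:].sort_values("delta", ascending=False)]
    ).reset_index(drop=True)


def risk_change_groups(pce_risks: pd.DataFrame, dl_risks: pd.DataFrame) -> pd.DataFrame:
    """Classify participants by whether the deep model moved their risk
    up or down relative to the reference; exact ties go to neither group."""
    merged = pce_risks.rename(columns={"risk_10y": "ref"})[["id", "ref"]].merge(
        dl_risks.rename(columns={"risk_10y": "new"})[["id", "new"]], on="id", how="outer"
    )
    if merged[["ref", "new"]].isna().any().any():
        raise ValueError("risk tables do not align on id")
    group = np.where(
        merged["new"] > merged["ref"],
        "risk_increased",
        np.where(merged["new"] < merged["ref"], "risk_decreased", "tie"),
    )
    return pd.DataFrame({"id": merged["id"], "group": group})


@dataclass
class TrajectorySummary:
    group: str
    factor: str
    table: pd.DataFrame  # time, mean, lo, hi
    slope: float
    slope_se: float


def group_trajectory_summary(
    cohort: CohortDataset,
    groups: pd.DataFrame,
    factor: str,
    times: np.ndarray | None = None,
    level: float = 0.95,
) -> dict[str, TrajectorySummary]:
    """Smoothed mean trajectory of one factor per risk-change group.

    Linear mean model of the factor on exam time, fit under working
    independence with cluster-robust (by participant) standard errors —
    the same point estimates a GEE with independence working
    correlation would give.  95% bands come from the robust covariance
    of the fitted mean, evaluated over the exam-time range.
    """
    exams = cohort.exams.merge(groups, on="id")
    out = {}
    for gname in ("risk_increased", "risk_decreased"):
        sub = exams[(exams["group"] == gname) & exams[f"{factor}_observed"]]
        if len(sub) == 0:
            raise ValueError(f"group {gname} is empty")
        if sub["exam_time_years"].nunique() < 2:
            raise ValueError(f"group {gname} has fewer than 2 distinct exam times")
        X = sm.add_constant(sub["exam_time_years"].to_numpy(float))
        y = sub[factor].to_numpy(float)
        if sub["id"].nunique() >= 2:
            fit = sm.OLS(y, X).fit(
                cov_type="cluster", cov_kwds={"groups": sub["id"].to_numpy()}
            )
        else:  # a single cluster: plain OLS covariance is the only option
            fit = sm.OLS(y, X).fit()
        t_eval = (
            np.linspace(sub["exam_time_years"].min(), sub["exam_time_years"].max(), 17)
            if times is None
            else np.asarray(times, float)
        )
        Xe = sm.add_constant(t_eval)
        mean = Xe @ fit.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xe, fit.cov_params(), Xe))
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        out[gname] = TrajectorySummary(
            group=gname,
            factor=factor,
            table=pd.DataFrame(
                {"time": t_eval, "mean": mean, "lo": mean - z * se, "hi": mean + z * se}
            ),
            slope=float(fit.params[1]),
            slope_se=float(np.sqrt(fit.cov_params()[1, 1])),
        )
    return out
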