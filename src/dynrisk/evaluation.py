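"""Discrimination, calibration, and reclassification metrics.

All metrics operate on 10-year binary labels derived from the
censored outcomes.  The primary censoring policy excludes subjects
censored before the horizon (transparent, unbiased under independent
censoring only for discrimination rankings); an inverse-probability-
of-censoring-weighted (IPCW) variant is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint


class MetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


# ---------------------------------------------------------------------------
# labels


def binary_labels_at_horizon(
    outcomes: pd.DataFrame, horizon: float = 10.0, policy: str = "exclude"
) -> pd.DataFrame:
    """10-year binary labels from censored outcomes.

    Event before or at the horizon -> label 1; followed event-free to
    the horizon -> label 0; censored strictly before the horizon ->
    excluded (``included=False``) under the primary policy.  With
    ``policy='ipcw'`` the same rows are flagged and inverse-probability-
    of-censoring weights (Kaplan-Meier of the censoring distribution)
    are attached to the included rows.
    """
    if (outcomes["time_years"] <= 0).any():
        raise ValueError("outcome times must be positive")
    t = outcomes["time_years"].to_numpy(float)
    e = outcomes["event"].to_numpy(int)
    is_event = (e == 1) & (t <= horizon)
    followed = t >= horizon
    included = is_event | followed
    out = pd.DataFrame(
        {
            "id": outcomes["id"].to_numpy(),
            "label": np.where(is_event, 1, 0),
            "included": included,
        }
    )
    out.loc[~included, "label"] = -1
    if policy == "ipcw":
        out["weight"] = _ipcw_weights(t, e, horizon, included, is_event)
    elif policy != "exclude":
        raise ValueError(f"unknown censoring policy {policy!r}")
    return out


def _ipcw_weights(t, e, horizon, included, is_event):
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(t, event_observed=1 - e)  # censoring distribution
    w = np.zeros(len(t))
    g_event = np.maximum(km.survival_function_at_times(np.minimum(t, horizon)).to_numpy(), 1e-8)
    g_h = max(float(km.survival_function_at_times(horizon).iloc[0]), 1e-8)
    w[is_event] = 1.0 / g_event[is_event]
    w[included & ~is_event] = 1.0 / g_h
    return w


# ---------------------------------------------------------------------------
# discrimination / calibration


def auroc(scores, labels, weights=None) -> float:
    """Probability a random event outranks a random non-event (ties 1/2).

    Computed by the rank/U-statistic identity, which is exactly the
    pairwise concordance with half-credit for ties.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(scores) != len(labels) or len(scores) == 0:
        raise MetricError("scores and labels must be non-empty and aligned")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MetricError("AUROC needs at least one event and one non-event")
    if weights is None:
        ranks = rankdata(scores)
        u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
        return float(u / (n1 * n0))
    # weighted pairwise form (used by the IPCW variant)
    w = np.asarray(weights, float)
    s1, w1 = scores[labels == 1], w[labels == 1]
    s0, w0 = scores[labels == 0], w[labels == 0]
    diff = s1[:, None] - s0[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    ww = w1[:, None] * w0[None, :]
    return float((conc * ww).sum() / ww.sum())


def brier(scores, labels, weights=None) -> float:
    """Mean squared difference between predicted risk and binary outcome."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if len(scores) == 0:
        raise MetricError("empty input")
    if np.any((scores < 0) | (scores > 1)):
        raise MetricError("scores must lie in [0, 1]")
    sq = (scores - labels) ** 2
    if weights is None:
        return float(sq.mean())
    w = np.asarray(weights, float)
    return float((sq * w).sum() / w.sum())


def continuous_nri(ref_scores, new_scores, labels) -> float:
    """Continuous net reclassification improvement of ``new`` vs ``ref``.

    [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)];
    exact ties contribute to neither direction.  Range [-2, 2].
    """
    ref = np.asarray(ref_scores, float)
    new = np.asarray(new_scores, float)
    labels = np.asarray(labels, int)
    if not (len(ref) == len(new) == len(labels)):
        raise MetricError("inputs must align")
    ev = labels == 1
    ne = labels == 0
    if ev.sum() == 0 or ne.sum() == 0:
        raise MetricError("continuous NRI needs events and non-events")
    up = new > ref
    down = new < ref
    nri_event = (up[ev].mean() - down[ev].mean())
    nri_nonevent = (down[ne].mean() - up[ne].mean())
    return float(nri_event + nri_nonevent)


def bootstrap_ci(metric_fn, data: pd.DataFrame, B: int = 500, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap over participants (rows of ``data``).

    ``metric_fn`` maps a DataFrame to a scalar.  Returns (lower, point,
    upper); the point estimate is the full-sample metric.  Errors in
    more than 10% of resamples raise MetricError.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    point = float(metric_fn(data))
    n = len(data)
    stats, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(float(metric_fn(data.iloc[idx])))
        except Exception:
            failures += 1
    if failures > 0.1 * B:
        raise MetricError(f"metric failed in {failures}/{B} bootstrap resamples")
    alpha = 1.0 - level
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), point, float(hi)


def calibration_deciles(scores, labels, ids=None, level: float = 0.95) -> pd.DataFrame:
    """Decile calibration table: mean predicted vs observed proportion.

    Participants are ranked into 10 equal-count bins; ties are broken
    by stable id order so constant scores still give equal bins.
    Observed-proportion CIs are Wilson intervals.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n = len(scores)
    if n < 10:
        raise MetricError("need at least 10 participants for deciles")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, scores))  # stable: score, then id
    rows = []
    for d, chunk in enumerate(np.array_split(order, 10), start=1):
        s, y = scores[chunk], labels[chunk]
        lo, hi = proportion_confint(y.sum(), len(y), alpha=1 - level, method="wilson")
        rows.append(
            {
                "decile": d,
                "n": len(chunk),
                "mean_predicted": float(s.mean()),
                "observed": float(y.mean()),
                "obs_lo": float(lo),
                "obs_hi": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroups / reclassification


SUBGROUP_DEFS = {
    "black_male": lambda s: (s["race"] == "black") & (s["sex"] == "male"),
    "black_female": lambda s: (s["race"] == "black") & (s["sex"] == "female"),
    "other_male": lambda s: (s["race"] != "black") & (s["sex"] == "male"),
    "other_female": lambda s: (s["race"] != "black") & (s["sex"] == "female"),
    "age_lt_60": lambda s: s["age_at_prediction"] < 60,
    "age_ge_60": lambda s: s["age_at_prediction"] >= 60,
}


def subgroup_evaluate(
    scored: pd.DataFrame,
    statics: pd.DataFrame,
    groups: list[str] | None = None,
    min_events: int = 10,
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC with bootstrap CI per subgroup.

    ``scored`` needs columns id, score, label (included rows only).
    Groups with fewer than ``min_events`` events in either class are
    reported with estimable=False rather than dropped.
    """
    groups = list(SUBGROUP_DEFS) if groups is None else groups
    unknown = set(groups) - set(SUBGROUP_DEFS)
    if unknown:
        raise ValueError(f"unknown subgroup keys: {sorted(unknown)}")
    merged = scored.merge(statics, on="id")
    rows = []
    for g in groups:
        sub = merged[SUBGROUP_DEFS[g](merged)]
        n_ev = int((sub["label"] == 1).sum())
        n_ne = int((sub["label"] == 0).sum())
        row = {"group": g, "n": len(sub), "n_events": n_ev}
        if n_ev < min_events or n_ne < min_events:
            row.update(estimable=False, auroc=np.nan, ci_lo=np.nan, ci_hi=np.nan)
        else:
            lo, point, hi = bootstrap_ci(
                lambda d: auroc(d["score"], d["label"]), sub, B=B, seed=seed
            )
            row.update(estimable=True, auroc=point, ci_lo=lo, ci_hi=hi)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReclassificationTable:
    """Bookkeeping of risk-threshold crossings between two models."""

    threshold: float
    cells: pd.DataFrame  # ref_above x new_above counts and event proportions
    n_ref_above: int
    n_ref_below: int
    n_down: int  # ref above, new below
    n_up: int  # ref below, new above
    frac_down: float
    frac_up: float
    event_free_frac_down: float  # among the down-movers
    event_frac_up: float  # among the up-movers


def reclassification_table(
    ref_risks, new_risks, labels, threshold: float = 0.075
) -> ReclassificationTable:
    """Four-cell table of 7.5%-threshold crossings, with the headline
    fractions: of those above threshold under the reference model, how
    many move below under the comparator (and how many of the movers
    stay event-free); of those below, how many move above (and how many
    of those develop the event)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ref = np.asarray(ref_risks, float)
    new = np.asarray(new_risks, float)
    labels = np.asarray(labels, int)
    if not (len(ref) == len(new) == len(labels)):
        raise ValueError("inputs must align")
    ra = ref >= threshold
    na = new >= threshold
    rows = []
    for r in (True, False):
        for c in (True, False):
            m = (ra == r) & (na == c)
            rows.append(
                {
                    "ref_above": r,
                    "new_above": c,
                    "count": int(m.sum()),
                    "event_prop": float(labels[m].mean()) if m.any() else np.nan,
                }
            )
    cells = pd.DataFrame(rows)
    down = ra & ~na
    up = ~ra & na
    return ReclassificationTable(
        threshold=threshold,
        cells=cells,
        n_ref_above=int(ra.sum()),
        n_ref_below=int((~ra).sum()),
        n_down=int(down.sum()),
        n_up=int(up.sum()),
        frac_down=float(down.sum() / max(ra.sum(), 1)),
        frac_up=float(up.sum() / max((~ra).sum(), 1)),
        event_free_frac_down=float((labels[down] == 0).mean()) if down.any() else np.nan,
        event_frac_up=float((labels[up] == 1).mean()) if up.any() else np.nan,
    )


# ---------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    model_name: str
    n: int
    n_events: int
    auroc: float
    auroc_ci: tuple[float, float]
    brier: float
    nri_vs_reference: float | None = None
    calibration: pd.DataFrame | None = None
    subgroups: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "model_name": self.model_name,
            "n": self.n,
            "n_events": self.n_events,
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "brier": self.brier,
        }
        if self.nri_vs_reference is not None:
            out["nri_vs_reference"] = self.nri_vs_reference
        if self.calibration is not None:
            out["calibration"] = self.calibration.to_dict(orient="records")
        if self.subgroups is not None:
            out["subgroups"] = self.subgroups.to_dict(orient="records")
        return out


def evaluate_model(
    risks: pd.DataFrame,
    outcomes: pd.DataFrame,
    statics: pd.DataFrame | None = None,
    model_name: str = "model",
    reference_risks: pd.DataFrame | None = None,
    horizon: float = 10.0,
    B: int = 500,
    seed: int = 0,
    with_subgroups: bool = False,
) -> EvalReport:
    """Full evaluation of one model's risk scores against outcomes."""
    labels = binary_labels_at_horizon(outcomes, horizon=horizon)
    merged = risks.merge(labels[labels["included"]], on="id")
    scored = pd.DataFrame(
        {"id": merged["id"], "score": merged["risk_10y"], "label": merged["label"]}
    )
    lo, point, hi = bootstrap_ci(lambda d: auroc(d["score"], d["label"]), scored, B=B, seed=seed)
    nri = None
    if reference_risks is not None:
        both = scored.merge(
            reference_risks.rename(columns={"risk_10y": "ref_score"})[["id", "ref_score"]], on="id"
        )
        nri = continuous_nri(both["ref_score"], both["score"], both["label"])
    report = EvalReport(
        model_name=model_name,
        n=len(scored),
        n_events=int((scored["label"] == 1).sum()),
        auroc=point,
        auroc_ci=(lo, hi),
        brier=brier(scored["score"], scored["label"]),
        nri_vs_reference=nri,
        calibration=calibration_deciles(scored["score"], scored["label"], ids=scored["id"]),
    )
    if with_subgroups and statics is not None:
        report.subgroups = subgroup_evaluate(scored, statics, seed=seed)
    return report
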