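"""Sequence encoding: longitudinal exams -> padded network input arrays.

Irregular exam histories are turned into fixed-shape arrays following
the standard recipe for irregular clinical sequences: forward-fill of
missing lab values within person (training-set median before the first
observation), an observed-mask channel per lab, and a time-since-
previous-exam channel; static covariates are broadcast to every step.
Continuous channels are standardized with training-set statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import FACTORS
from ..synthetic_cohort import CohortDataset

#: static model features, canonical order
STATIC_FEATURES = ("age", "male", "black", "smoker", "diabetes", "htn_treatment")
#: all removable features (leave-one-out importance operates on these)
ALL_FEATURES = tuple(FACTORS) + STATIC_FEATURES

_STATIC_COLS = {
    "age": ("age_at_prediction", False),
    "male": ("sex", True),
    "black": ("race", True),
    "smoker": ("smoker", True),
    "diabetes": ("diabetes", True),
    "htn_treatment": ("htn_treatment", True),
}


@dataclass
class Standardizer:
    """Training-set means/sds/medians for the continuous channels."""

    means: dict[str, float]
    sds: dict[str, float]
    medians: dict[str, float]

    @classmethod
    def fit(cls, cohort: CohortDataset) -> "Standardizer":
        means, sds, medians = {}, {}, {}
        for f in FACTORS:
            vals = cohort.exams.loc[cohort.exams[f"{f}_observed"], f]
            means[f] = float(vals.mean())
            sds[f] = float(vals.std()) or 1.0
            medians[f] = float(vals.median())
        age = cohort.statics["age_at_prediction"]
        means["age"] = float(age.mean())
        sds["age"] = float(age.std()) or 1.0
        medians["age"] = float(age.median())
        return cls(means=means, sds=sds, medians=medians)

    def transform(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]


@dataclass
class EncodedBatch:
    """Padded arrays for a batch of participants.

    x: (N, L, d_in) step inputs; valid: (N, L) step validity;
    last_cov: (N, d_last) last-exam covariates for the cause network;
    next_target/next_mask: (N, L, n_cont) step-ahead regression targets
    (standardized next-exam values) and their scoring mask.
    """

    ids: np.ndarray
    x: np.ndarray
    valid: np.ndarray
    last_cov: np.ndarray
    next_target: np.ndarray
    next_mask: np.ndarray
    feature_names: tuple[str, ...] = ()
    cont_features: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def take(self, idx) -> "EncodedBatch":
        return EncodedBatch(
            ids=self.ids[idx],
            x=self.x[idx],
            valid=self.valid[idx],
            last_cov=self.last_cov[idx],
            next_target=self.next_target[idx],
            next_mask=self.next_mask[idx],
            feature_names=self.feature_names,
            cont_features=self.cont_features,
        )


def encode_cohort(
    cohort: CohortDataset,
    standardizer: Standardizer,
    exclude: set[str] | frozenset[str] = frozenset(),
    max_len: int = 4,
) -> EncodedBatch:
    """Encode every participant of a cohort into an EncodedBatch.

    ``exclude`` removes features jointly from all channels: a lab factor
    loses its value, mask, and step-ahead target; a static feature is
    dropped from both the per-step broadcast and the last-exam vector.
    """
    unknown = set(exclude) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features to exclude: {sorted(unknown)}")
    cont = tuple(f for f in FACTORS if f not in exclude)
    statics = tuple(s for s in STATIC_FEATURES if s not in exclude)
    n_cont = len(cont)
    d_in = 2 * n_cont + 1 + len(statics)  # values + masks + delta + statics
    d_last = n_cont + len(statics)

    s = cohort.statics.set_index("id")
    static_mat = np.zeros((len(s), len(statics)))
    for j, name in enumerate(statics):
        col, is_binary = _STATIC_COLS[name]
        if name == "male":
            static_mat[:, j] = (s[col] == "male").to_numpy(float)
        elif name == "black":
            static_mat[:, j] = (s[col] == "black").to_numpy(float)
        elif is_binary:
            static_mat[:, j] = s[col].to_numpy(bool).astype(float)
        else:
            static_mat[:, j] = standardizer.transform(name, s[col].to_numpy(float))
    static_by_id = dict(zip(s.index, static_mat))

    ids = cohort.statics["id"].to_numpy()
    N = len(ids)
    x = np.zeros((N, max_len, d_in))
    valid = np.zeros((N, max_len), dtype=bool)
    last_cov = np.zeros((N, d_last))
    next_target = np.zeros((N, max_len, n_cont))
    next_mask = np.zeros((N, max_len, n_cont), dtype=bool)

    exams = cohort.exams.sort_values(["id", "exam_time_years"])
    grouped = dict(tuple(exams.groupby("id")))
    med = np.array([standardizer.transform(f, standardizer.medians[f]) for f in cont])

    for i, pid in enumerate(ids):
        g = grouped.get(pid)
        if g is None or len(g) == 0:
            raise ValueError(f"participant {pid} has no exams")
        L = min(len(g), max_len)
        g = g.iloc[-L:]
        times = g["exam_time_years"].to_numpy(float)
        obs = g[[f"{f}_observed" for f in cont]].to_numpy(bool)
        vals = np.stack([standardizer.transform(f, g[f].to_numpy(float)) for f in cont], axis=1)
        # forward fill in standardized space; median before first observation
        filled = np.empty_like(vals)
        carry = med.copy()
        for t in range(L):
            carry = np.where(obs[t], vals[t], carry)
            filled[t] = carry
        delta = np.diff(times, prepend=times[0])
        sv = static_by_id[pid]
        x[i, :L] = np.concatenate(
            [filled, obs.astype(float), delta[:, None], np.tile(sv, (L, 1))], axis=1
        )
        valid[i, :L] = True
        last_cov[i] = np.concatenate([filled[-1], sv])
        if L > 1:
            next_target[i, : L - 1] = filled[1:]
            next_mask[i, : L - 1] = obs[1:]

    return EncodedBatch(
        ids=ids,
        x=x,
        valid=valid,
        last_cov=last_cov,
        next_target=next_target,
        next_mask=next_mask,
        feature_names=cont + statics,
        cont_features=cont,
    )


def encode_history(series: pd.DataFrame, static_row: pd.Series, standardizer: Standardizer,
                   exclude: set[str] | frozenset[str] = frozenset()) -> EncodedBatch:
    """Encode a single participant (long-format exam rows + static row)."""
    if len(series) == 0:
        raise ValueError("empty exam series")
    cohort = CohortDataset(
        statics=pd.DataFrame([static_row]),
        exams=series.copy(),
        outcomes=pd.DataFrame({"id": [static_row["id"]], "time_years": [1.0], "event": [0]}),
    )
    return encode_cohort(cohort, standardizer, exclude=exclude)
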