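"""Configuration objects for cohort simulation and experiment runs.

All configs round-trip through YAML.  The packaged default simulation
config (``dynrisk/data/default_simulation.yaml``) encodes the study
conditions the rest of the package is exercised under: repeated
correlated risk-factor exams inside an 8-year observation window,
hazards driven by last-exam levels and 8-year slopes, and a ~13.9%
ten-year event fraction at the reference cohort size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

#: longitudinal lab factors, in canonical order
FACTORS = ("sbp", "dbp", "tc", "hdl")

#: static covariates carried through the models
STATIC_BINARY = ("male", "black", "smoker", "diabetes", "htn_treatment")

#: physiologic clipping ranges (keeps PCE log-transforms finite)
PHYSIOLOGIC_RANGES: Mapping[str, tuple[float, float]] = {
    "sbp": (70.0, 250.0),
    "dbp": (40.0, 150.0),
    "tc": (80.0, 500.0),
    "hdl": (10.0, 150.0),
}


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    Continuous hazard covariates are centred (factors at ``factor_means``,
    age at ``age_center``) so ``baseline_hazard`` is the event rate, in
    events per person-year, of a reference participant.
    """

    n_participants: int = 15565
    #: probability of 1, 2, 3, 4 exams inside the 8-year window
    schedule_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.40, 3: 0.30, 4: 0.15}
    )
    factor_means: dict[str, float] = field(
        default_factory=lambda: {"sbp": 121.0, "dbp": 74.8, "tc": 207.0, "hdl": 51.6}
    )
    factor_sds: dict[str, float] = field(
        default_factory=lambda: {"sbp": 17.0, "dbp": 10.5, "tc": 40.0, "hdl": 15.5}
    )
    #: between-person slope standard deviations, units per year
    slope_sds: dict[str, float] = field(
        default_factory=lambda: {"sbp": 1.2, "dbp": 0.7, "tc": 2.0, "hdl": 0.6}
    )
    #: exam-level measurement noise, same units as the factor
    noise_sds: dict[str, float] = field(
        default_factory=lambda: {"sbp": 6.0, "dbp": 4.0, "tc": 10.0, "hdl": 4.0}
    )
    #: correlation of the person-level factor baselines, FACTORS order
    factor_correlation: list[list[float]] = field(
        default_factory=lambda: [
            [1.00, 0.60, 0.15, -0.10],
            [0.60, 1.00, 0.15, -0.05],
            [0.15, 0.15, 1.00, 0.10],
            [-0.10, -0.05, 0.10, 1.00],
        ]
    )
    #: log-hazard coefficients on last-exam values, 8-year slopes, statics
    hazard_coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "last": {"sbp": 0.015, "dbp": 0.0, "tc": 0.004, "hdl": -0.020},
            "slope": {"sbp": 0.10, "dbp": 0.0, "tc": 0.02, "hdl": 0.0},
            "static": {
                "age": 0.07,
                "male": 0.40,
                "black": 0.05,
                "smoker": 0.45,
                "diabetes": 0.70,
                "htn_treatment": 0.25,
            },
        }
    )
    baseline_hazard: float = 0.0081  # events / person-year for the reference profile
    censoring_rate: float = 0.02  # independent censoring, per person-year
    horizon: float = 10.0  # years of outcome follow-up
    age_mean: float = 50.2
    age_sd: float = 7.2
    age_center: float = 50.0
    age_bounds: tuple[float, float] = (40.5, 74.5)
    p_female: float = 0.548
    p_black: float = 0.270
    p_smoker: float = 0.297
    p_diabetes: float = 0.091
    p_htn_treatment: float = 0.239
    p_prior_ascvd: float = 0.0  # fraction flagged with an observation-window event
    missing_rate: float = 0.03  # per factor per exam
    observation_window: float = 8.0  # years of exam history before prediction
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        probs = np.asarray(list(self.schedule_mix.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("schedule_mix probabilities must sum to 1")
        if any(k < 1 or k > 4 for k in self.schedule_mix):
            raise ConfigurationError("schedule_mix supports 1-4 exams")
        corr = np.asarray(self.factor_correlation, dtype=float)
        if corr.shape != (len(FACTORS), len(FACTORS)):
            raise ConfigurationError("factor_correlation must be 4x4")
        if not np.allclose(corr, corr.T):
            raise ConfigurationError("factor_correlation must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("factor_correlation must be positive semi-definite")
        for name in ("baseline_hazard", "censoring_rate", "missing_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "schedule_mix" in raw:
            raw = dict(raw)
            raw["schedule_mix"] = {int(k): float(v) for k, v in raw["schedule_mix"].items()}
        if "age_bounds" in raw:
            raw["age_bounds"] = tuple(raw["age_bounds"])
        return cls(**raw)


def _plain(obj):
    """Recursively convert numpy scalars/tuples so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def default_simulation_config(**overrides) -> SimulationConfig:
    """The packaged default study conditions, optionally overridden."""
    path = resources.files("dynrisk.data") / "default_simulation.yaml"
    with resources.as_file(path) as p:
        cfg = SimulationConfig.from_yaml(p)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def slope_signal_config(n_participants: int = 5000, seed: int = 0) -> SimulationConfig:
    """Study condition with slope-dependent hazards: four exams per
    participant and a strong SBP-slope effect on the log hazard, next to
    a modest last-value effect.  The trajectory carries information the
    last exam alone cannot, so a longitudinal model should discriminate
    better than a cross-sectional one here."""
    zero = {f: 0.0 for f in FACTORS}
    return SimulationConfig(
        n_participants=n_participants,
        schedule_mix={4: 1.0},
        slope_sds={"sbp": 2.0, "dbp": 0.7, "tc": 2.0, "hdl": 0.6},
        hazard_coefs={
            "last": {**zero, "sbp": 0.010},
            "slope": {**zero, "sbp": 0.30},
            "static": {},
        },
        baseline_hazard=0.012,
        seed=seed,
    )


def last_value_config(n_participants: int = 5000, seed: int = 0) -> SimulationConfig:
    """Counterpart of the slope-signal condition with all slope
    coefficients zero: the last exam carries every bit of hazard
    information, so longitudinal and cross-sectional models should be
    statistically indistinguishable."""
    cfg = slope_signal_config(n_participants=n_participants, seed=seed)
    cfg.hazard_coefs["slope"] = {f: 0.0 for f in FACTORS}
    cfg.hazard_coefs["last"] = {**cfg.hazard_coefs["last"], "sbp": 0.03}
    return cfg


def planted_sbp_config(n_participants: int = 3000, seed: int = 0) -> SimulationConfig:
    """Study condition where SBP (level and slope) is the sole hazard
    driver; every other feature is pure noise.  Used by the
    leave-one-out importance analysis, which should rank SBP first."""
    zero = {f: 0.0 for f in FACTORS}
    return SimulationConfig(
        n_participants=n_participants,
        slope_sds={"sbp": 2.0, "dbp": 0.7, "tc": 2.0, "hdl": 0.6},
        hazard_coefs={
            "last": {**zero, "sbp": 0.030},
            "slope": {**zero, "sbp": 0.25},
            "static": {},
        },
        baseline_hazard=0.012,
        seed=seed,
    )
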