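"""End-to-end experiment orchestration: simulate -> filter -> split ->
train (PCE, cross-sectional, dynamic) -> evaluate -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pce as pce_mod
from .config import SimulationConfig, default_simulation_config
from .deep_survival import SurvivalNetConfig, train
from .evaluation import evaluate_model, reclassification_table
from .importance import group_trajectory_summary, loo_importance, risk_change_groups
from .synthetic_cohort import CohortDataset, apply_eligibility, simulate_cohort

log = logging.getLogger("dynrisk")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=default_simulation_config)
    data_dir: str | None = None  # read existing CSVs instead of simulating
    split_ratios: tuple[float, float, float] = (3.0, 1.0, 1.0)
    dynamic: SurvivalNetConfig = field(default_factory=lambda: SurvivalNetConfig(mode="dynamic"))
    cross_sectional: SurvivalNetConfig = field(
        default_factory=lambda: SurvivalNetConfig(mode="cross_sectional")
    )
    threshold: float = 0.075
    bootstrap_B: int = 500
    with_subgroups: bool = True
    with_importance: bool = False
    with_trajectories: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        for key in ("dynamic", "cross_sectional"):
            if key in kwargs:
                kwargs[key] = SurvivalNetConfig(**kwargs[key])
        if "split_ratios" in kwargs:
            kwargs["split_ratios"] = tuple(kwargs["split_ratios"])
        return cls(**kwargs)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def split_dataset(
    cohort: CohortDataset, ratios: tuple[float, float, float] = (3, 1, 1), seed: int = 0
) -> pd.DataFrame:
    """Random participant-level train/tune/test assignment.

    Counts follow the ratios by the largest-remainder rule; the split is
    exhaustive, mutually exclusive, and reproducible under the seed.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = cohort.n
    if n < 5:
        raise ValueError("need at least 5 participants to split")
    total = sum(ratios)
    exact = np.array([n * r / total for r in ratios])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    ids = rng.permutation(cohort.ids)
    parts = np.split(ids, np.cumsum(counts)[:-1])
    rows = []
    for name, part in zip(("train", "tune", "test"), parts):
        rows.extend((pid, name) for pid in part)
    return pd.DataFrame(rows, columns=["id", "split"]).sort_values("id").reset_index(drop=True)


def _part(cohort: CohortDataset, splits: pd.DataFrame, name: str) -> CohortDataset:
    return cohort.subset(splits.loc[splits["split"] == name, "id"])


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and persist every artifact to ``out_dir``.

    PCE is fit on train+tune; the deep models train on train with early
    stopping on tune; every model is scored on the held-out test set
    only.  Returns the report dict (also written as report.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    stage = "setup"
    try:
        # provenance
        cfg_yaml = yaml.safe_dump(_config_dict(config), sort_keys=False)
        (out / "run_config.yaml").write_text(cfg_yaml)
        cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]

        stage = "simulate"
        if config.data_dir is not None:
            cohort = CohortDataset.from_csv(config.data_dir)
            tallies = {}
        else:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=derive_seed(config.seed, "simulate")
            )
            cohort = simulate_cohort(sim_cfg)
            cohort, tallies = apply_eligibility(cohort)
        cohort.to_csv(out)
        log.info("cohort: n=%d exclusions=%s", cohort.n, tallies)

        stage = "split"
        splits = split_dataset(cohort, config.split_ratios, derive_seed(config.seed, "split"))
        splits.to_csv(out / "splits.csv", index=False)
        tr, tu, te = (_part(cohort, splits, s) for s in ("train", "tune", "test"))

        stage = "fit_pce"
        pce_train = cohort.subset(splits.loc[splits["split"] != "test", "id"])
        coeffs = pce_mod.fit_pce_cox(pce_train)
        pce_mod.save_coefficients(coeffs, out / "pce_coefficients.json")
        risks_pce = pce_mod.score_cohort(te, coeffs)
        risks_pce["model_name"] = "pce"
        risks_pce.to_csv(out / "risks_pce.csv", index=False)

        stage = "train_dynamic"
        dyn_cfg = dataclasses.replace(config.dynamic, seed=derive_seed(config.seed, "dynamic"))
        dyn = train(dyn_cfg, tr, tu)
        risks_dyn = dyn.predict_risk_frame(te, "dynamic")
        risks_dyn.to_csv(out / "risks_dynamic.csv", index=False)

        stage = "train_cross_sectional"
        cs_cfg = dataclasses.replace(
            config.cross_sectional, seed=derive_seed(config.seed, "cross_sectional")
        )
        cs = train(cs_cfg, tr, tu)
        risks_cs = cs.predict_risk_frame(te, "cross_sectional")
        risks_cs.to_csv(out / "risks_cross_sectional.csv", index=False)

        stage = "evaluate"
        eval_seed = derive_seed(config.seed, "evaluate")
        reports = {}
        for name, risks, ref in (
            ("pce", risks_pce, None),
            ("cross_sectional", risks_cs, risks_pce),
            ("dynamic", risks_dyn, risks_pce),
        ):
            reports[name] = evaluate_model(
                risks,
                te.outcomes,
                statics=te.statics,
                model_name=name,
                reference_risks=ref,
                horizon=config.simulation.horizon,
                B=config.bootstrap_B,
                seed=eval_seed,
                with_subgroups=config.with_subgroups,
            )
        reports["dynamic"].calibration.to_csv(out / "calibration_dynamic.csv", index=False)
        reports["pce"].calibration.to_csv(out / "calibration_pce.csv", index=False)

        stage = "reclassification"
        from .evaluation import binary_labels_at_horizon

        labels = binary_labels_at_horizon(te.outcomes, horizon=config.simulation.horizon)
        both = (
            risks_pce.rename(columns={"risk_10y": "ref"})[["id", "ref"]]
            .merge(risks_dyn.rename(columns={"risk_10y": "new"})[["id", "new"]], on="id")
            .merge(labels[labels["included"]], on="id")
        )
        reclass = reclassification_table(both["ref"], both["new"], both["label"], config.threshold)
        reclass.cells.to_csv(out / "reclassification.csv", index=False)

        report = {
            "config_hash": cfg_hash,
            "seed": config.seed,
            "n": cohort.n,
            "n_test": te.n,
            "exclusions": tallies,
            "models": {k: v.to_dict() for k, v in reports.items()},
            "reclassification": {
                "threshold": reclass.threshold,
                "n_ref_above": reclass.n_ref_above,
                "n_down": reclass.n_down,
                "frac_down": reclass.frac_down,
                "event_free_frac_down": reclass.event_free_frac_down,
                "n_ref_below": reclass.n_ref_below,
                "n_up": reclass.n_up,
                "frac_up": reclass.frac_up,
                "event_frac_up": reclass.event_frac_up,
            },
        }

        if config.with_importance:
            stage = "importance"
            imp = loo_importance(
                dyn_cfg, tr, tu, te, B=config.bootstrap_B, seed=derive_seed(config.seed, "loo")
            )
            imp.to_csv(out / "importance.csv", index=False)
            report["importance"] = imp.to_dict(orient="records")

        if config.with_trajectories:
            stage = "trajectories"
            groups = risk_change_groups(risks_pce, risks_dyn)
            traj_rows = []
            for factor in ("sbp", "dbp", "tc", "hdl"):
                for g, summ in group_trajectory_summary(te, groups, factor).items():
                    t = summ.table.copy()
                    t.insert(0, "factor", factor)
                    t.insert(0, "group", g)
                    traj_rows.append(t)
            pd.concat(traj_rows).to_csv(out / "trajectories.csv", index=False)

        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "report.md").write_text(_report_markdown(report))
        return report
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None
    finally:
        log.removeHandler(fh)
        fh.close()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["split_ratios"] = list(d["split_ratios"])
    for key in ("dynamic", "cross_sectional"):
        d[key]["fc_hidden"] = list(d[key]["fc_hidden"])
    d["simulation"]["age_bounds"] = list(d["simulation"]["age_bounds"])
    return d


def _report_markdown(report: dict) -> str:
    lines = [
        "# dynrisk experiment report",
        "",
        f"config hash: `{report['config_hash']}`  seed: {report['seed']}",
        f"cohort n = {report['n']}, test n = {report['n_test']}",
        "",
        "| model | AUROC (95% CI) | Brier | NRI vs PCE |",
        "|---|---|---|---|",
    ]
    for name, m in report["models"].items():
        ci = m["auroc_ci"]
        nri = m.get("nri_vs_reference")
        lines.append(
            f"| {name} | {m['auroc']:.3f} ({ci[0]:.3f}-{ci[1]:.3f}) | {m['brier']:.4f} | "
            + (f"{nri:.3f} |" if nri is not None else "- |")
        )
    r = report["reclassification"]
    lines += [
        "",
        f"Reclassification at {r['threshold']:.1%}: of {r['n_ref_above']} above threshold "
        f"under PCE, {r['n_down']} ({r['frac_down']:.0%}) move below under the dynamic model "
        f"({r['event_free_frac_down']:.0%} of movers event-free); of {r['n_ref_below']} below, "
        f"{r['n_up']} ({r['frac_up']:.0%}) move above ({r['event_frac_up']:.0%} with events).",
    ]
    return "\n".join(lines) + "\n"


def auroc_by_mode(
    sim_config: SimulationConfig,
    seed: int,
    net_overrides: dict | None = None,
) -> dict:
    """Train the dynamic and cross-sectional networks on one simulated
    cohort (3:1:1 split) and return their test AUROCs.

    The two modes share the simulated data, the split, and the training
    seed, so the comparison isolates the value of the exam history."""
    from .evaluation import auroc, binary_labels_at_horizon

    net_overrides = net_overrides or {}
    cohort = simulate_cohort(dataclasses.replace(sim_config, seed=derive_seed(seed, "simulate")))
    cohort, _ = apply_eligibility(cohort)
    splits = split_dataset(cohort, (3, 1, 1), derive_seed(seed, "split"))
    tr, tu, te = (_part(cohort, splits, s) for s in ("train", "tune", "test"))
    labels = binary_labels_at_horizon(te.outcomes, horizon=sim_config.horizon)
    inc = labels["included"].to_numpy()
    out = {"n_test": int(inc.sum()), "seed": seed}
    for mode in ("dynamic", "cross_sectional"):
        cfg = SurvivalNetConfig(mode=mode, seed=derive_seed(seed, "net"), **net_overrides)
        model = train(cfg, tr, tu)
        risks = model.predict_risk(te)
        out[mode] = auroc(risks[inc], labels.loc[inc, "label"])
    return out
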