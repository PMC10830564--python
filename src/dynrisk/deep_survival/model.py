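"""Training loop and model object for the dynamic survival network."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import grad

from ..synthetic_cohort import CohortDataset
from .encoding import EncodedBatch, Standardizer, encode_cohort
from .grid import TimeGrid, cif_at
from .losses import composite_loss
from .network import full_forward, init_params


class TrainingError(RuntimeError):
    pass


@dataclass
class SurvivalNetConfig:
    rnn_hidden: int = 32
    rnn_layers: int = 1
    fc_hidden: tuple[int, ...] = (32,)
    dropout: float = 0.1
    alpha: float = 0.1  # ranking-loss weight
    beta: float = 0.1  # step-ahead prediction-loss weight
    sigma: float = 0.1  # ranking kernel scale
    learning_rate: float = 5e-3
    max_epochs: int = 60
    patience: int = 5
    batch_size: int = 256
    seed: int = 0
    mode: str = "dynamic"  # or "cross_sectional"
    n_bins: int = 20
    horizon: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.mode not in ("dynamic", "cross_sectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cross_sectional":
            self.beta = 0.0  # no sequence, no step-ahead targets
        self.fc_hidden = tuple(self.fc_hidden)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(horizon=self.horizon, n_bins=self.n_bins)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    tune_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class SurvivalModel:
    """A trained network plus everything needed to score new cohorts."""

    config: SurvivalNetConfig
    params: dict[str, np.ndarray]
    standardizer: Standardizer
    exclude: frozenset[str]
    history: TrainingHistory | None = None

    @property
    def grid(self) -> TimeGrid:
        return self.config.grid

    def encode(self, cohort: CohortDataset) -> EncodedBatch:
        return encode_cohort(cohort, self.standardizer, exclude=self.exclude)

    def forward(self, batch: EncodedBatch):
        """Deterministic (evaluation-mode) forward pass."""
        return full_forward(self.params, batch, self.config, dropout_masks=None)

    def predict_risk(self, cohort: CohortDataset, t: float | None = None) -> np.ndarray:
        """Cumulative incidence at time t (default: the horizon) per participant."""
        if not self.params:
            raise RuntimeError("model has no trained parameters")
        t = self.config.horizon if t is None else t
        batch = self.encode(cohort)
        probs, _, _ = self.forward(batch)
        return np.asarray(cif_at(np.asarray(probs), t, self.grid))

    def predict_risk_frame(self, cohort: CohortDataset, model_name: str, t: float | None = None):
        import pandas as pd

        risks = self.predict_risk(cohort, t)
        return pd.DataFrame(
            {"id": cohort.statics["id"].to_numpy(), "risk_10y": risks, "model_name": model_name}
        )

    # -- checkpoint io ----------------------------------------------------
    def save(self, path) -> None:
        header = {
            "config": dataclasses.asdict(self.config),
            "standardizer": dataclasses.asdict(self.standardizer),
            "exclude": sorted(self.exclude),
        }
        np.savez(
            path,
            __header__=np.array(json.dumps(header)),
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path, expect_config: SurvivalNetConfig | None = None) -> "SurvivalModel":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["__header__"]))
            params = {k[6:]: data[k] for k in data.files if k.startswith("param_")}
        cfg_dict = header["config"]
        cfg_dict["fc_hidden"] = tuple(cfg_dict["fc_hidden"])
        config = SurvivalNetConfig(**cfg_dict)
        if expect_config is not None and dataclasses.asdict(expect_config) != dataclasses.asdict(config):
            raise ValueError("checkpoint config does not match the expected config")
        return cls(
            config=config,
            params=params,
            standardizer=Standardizer(**header["standardizer"]),
            exclude=frozenset(header["exclude"]),
        )


def _adam_step(params, grads, m, v, step, lr, b1=0.9, b2=0.999, eps=1e-8):
    for k in params:
        m[k] = b1 * m[k] + (1 - b1) * grads[k]
        v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
        mhat = m[k] / (1 - b1**step)
        vhat = v[k] / (1 - b2**step)
        params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)


def train(
    config: SurvivalNetConfig,
    train_cohort: CohortDataset,
    tune_cohort: CohortDataset,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> SurvivalModel:
    """Fit the network by Adam on the composite loss with early stopping.

    Standardization constants come from the training cohort only; the
    tuning cohort drives early stopping (best-epoch weights returned).
    """
    if tune_cohort.n == 0:
        raise ValueError("tuning set must be non-empty")
    overlap = set(train_cohort.ids) & set(tune_cohort.ids)
    if overlap:
        raise ValueError("train and tune sets must be disjoint")
    exclude = frozenset(exclude)
    rng = np.random.default_rng(config.seed)
    grid = config.grid

    standardizer = Standardizer.fit(train_cohort)
    tr = encode_cohort(train_cohort, standardizer, exclude=exclude)
    tu = encode_cohort(tune_cohort, standardizer, exclude=exclude)
    tr_time = train_cohort.outcomes.set_index("id").loc[tr.ids, "time_years"].to_numpy()
    tr_event = train_cohort.outcomes.set_index("id").loc[tr.ids, "event"].to_numpy()
    tu_time = tune_cohort.outcomes.set_index("id").loc[tu.ids, "time_years"].to_numpy()
    tu_event = tune_cohort.outcomes.set_index("id").loc[tu.ids, "event"].to_numpy()

    n_cont = len(tr.cont_features)
    d_in = tr.x.shape[2]
    d_last = tr.last_cov.shape[1]
    params = init_params(
        rng,
        d_in=d_in,
        d_last=d_last,
        n_cont=n_cont,
        rnn_hidden=config.rnn_hidden,
        rnn_layers=config.rnn_layers,
        fc_hidden=config.fc_hidden,
        n_out=config.n_bins + 1,
        mode=config.mode,
    )

    def batch_loss(p, batch, time, event, masks):
        probs, preds, _ = full_forward(p, batch, config, dropout_masks=masks)
        return composite_loss(
            probs, preds, batch, time, event, grid, config.alpha, config.beta, config.sigma
        )

    loss_grad = grad(batch_loss)

    def tune_loss(p):
        return float(batch_loss(p, tu, tu_time, tu_event, None))

    m = {k: np.zeros_like(x) for k, x in params.items()}
    v = {k: np.zeros_like(x) for k, x in params.items()}
    history = TrainingHistory()
    best = {k: x.copy() for k, x in params.items()}
    best_loss = np.inf
    step = 0
    stale = 0
    n = tr.n
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = tr.take(idx)
            masks = None
            if config.dropout > 0:
                masks = [
                    (rng.random((len(idx), h)) >= config.dropout) / (1 - config.dropout)
                    for h in config.fc_hidden
                ]
            cur = batch_loss(params, batch, tr_time[idx], tr_event[idx], masks)
            if not np.isfinite(cur):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            grads = loss_grad(params, batch, tr_time[idx], tr_event[idx], masks)
            step += 1
            _adam_step(params, grads, m, v, step, config.learning_rate)
            epoch_losses.append(float(cur))
        history.train_loss.append(float(np.mean(epoch_losses)))
        tl = tune_loss(params)
        if not np.isfinite(tl):
            raise TrainingError(f"non-finite tuning loss at epoch {epoch}")
        history.tune_loss.append(tl)
        if tl < best_loss - 1e-6:
            best_loss = tl
            best = {k: x.copy() for k, x in params.items()}
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    return SurvivalModel(
        config=config,
        params=best,
        standardizer=standardizer,
        exclude=exclude,
        history=history,
    )
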