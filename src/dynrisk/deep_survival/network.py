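"""Network forward passes (autograd-differentiable numpy).

Architecture: a shared GRU encoder over the exam sequence that also
emits step-ahead predictions of the next exam's lab values, a masked
additive-attention pooling of the hidden states, and a cause-specific
fully connected head whose softmax output spans the discrete time bins
plus one terminal event-free slot.  The cross-sectional variant feeds
only the last-exam covariates to the cause head.

Parameters live in a flat dict of numpy arrays so `autograd.grad`
differentiates the composite loss end to end.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    rng: np.random.Generator,
    d_in: int,
    d_last: int,
    n_cont: int,
    rnn_hidden: int,
    rnn_layers: int,
    fc_hidden: tuple[int, ...],
    n_out: int,
    mode: str,
) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    if mode == "dynamic":
        d = d_in
        for layer in range(rnn_layers):
            for gate in ("z", "r", "h"):
                p[f"W{gate}{layer}"] = _glorot(rng, (d, rnn_hidden))
                p[f"U{gate}{layer}"] = _glorot(rng, (rnn_hidden, rnn_hidden))
                p[f"b{gate}{layer}"] = np.zeros(rnn_hidden)
            d = rnn_hidden
        p["Wpred"] = _glorot(rng, (rnn_hidden, n_cont))
        p["bpred"] = np.zeros(n_cont)
        p["Watt"] = _glorot(rng, (rnn_hidden, rnn_hidden))
        p["batt"] = np.zeros(rnn_hidden)
        p["vatt"] = _glorot(rng, (rnn_hidden,))
        d_cause = rnn_hidden + d_last
    else:
        d_cause = d_last
    d = d_cause
    for k, h in enumerate(fc_hidden):
        p[f"Wfc{k}"] = _glorot(rng, (d, h))
        p[f"bfc{k}"] = np.zeros(h)
        d = h
    p["Wout"] = _glorot(rng, (d, n_out))
    p["bout"] = np.zeros(n_out)
    return p


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def shared_forward(params, x, valid, rnn_layers: int):
    """GRU encoder: returns hidden states (N, L, H) and step-ahead
    predictions (N, L, n_cont).  Padded steps carry the previous hidden
    state forward and are masked out of every downstream quantity."""
    N, L, _ = x.shape
    inp = x
    H = None
    for layer in range(rnn_layers):
        h = anp.zeros((N, params[f"Uz{layer}"].shape[0]))
        states = []
        for t in range(L):
            xt = inp[:, t, :]
            z = _sigmoid(xt @ params[f"Wz{layer}"] + h @ params[f"Uz{layer}"] + params[f"bz{layer}"])
            r = _sigmoid(xt @ params[f"Wr{layer}"] + h @ params[f"Ur{layer}"] + params[f"br{layer}"])
            hh = anp.tanh(xt @ params[f"Wh{layer}"] + (r * h) @ params[f"Uh{layer}"] + params[f"bh{layer}"])
            h_new = (1.0 - z) * h + z * hh
            mask = valid[:, t][:, None]
            h = anp.where(mask, h_new, h)
            states.append(h)
        H = anp.stack(states, axis=1)
        inp = H
    preds = H @ params["Wpred"] + params["bpred"]
    return H, preds


def attention_context(params, hidden, valid):
    """Masked additive attention pooling.

    Weights are non-negative, zero on invalid steps, and sum to one
    over valid steps; the context is the weighted sum of hidden states.
    """
    valid = np.asarray(valid, dtype=bool)
    if not valid.any(axis=1).all():
        raise ValueError("every sequence needs at least one valid step")
    scores = anp.tanh(hidden @ params["Watt"] + params["batt"]) @ params["vatt"]  # (N, L)
    scores = anp.where(valid, scores, -1e30)
    scores = scores - anp.max(scores, axis=1, keepdims=True)
    w = anp.exp(scores) * valid
    w = w / anp.sum(w, axis=1, keepdims=True)
    context = anp.sum(w[:, :, None] * hidden, axis=1)
    return context, w


def cause_forward(params, cause_input, fc_hidden: tuple[int, ...],
                  dropout_masks=None):
    """Fully connected cause head ending in a softmax over
    n_bins + 1 slots (per-bin event probability + terminal mass)."""
    h = cause_input
    for k in range(len(fc_hidden)):
        h = anp.maximum(0.0, h @ params[f"Wfc{k}"] + params[f"bfc{k}"])
        if dropout_masks is not None:
            h = h * dropout_masks[k]
    logits = h @ params["Wout"] + params["bout"]
    logits = logits - anp.max(logits, axis=1, keepdims=True)
    e = anp.exp(logits)
    return e / anp.sum(e, axis=1, keepdims=True)


def full_forward(params, batch, config, dropout_masks=None):
    """End-to-end forward pass; returns (probs, step_preds, attention_weights)."""
    if config.mode == "dynamic":
        H, preds = shared_forward(params, batch.x, batch.valid, config.rnn_layers)
        context, w = attention_context(params, H, batch.valid)
        cause_in = anp.concatenate([context, batch.last_cov], axis=1)
    else:
        preds, w = None, None
        cause_in = batch.last_cov
    probs = cause_forward(params, cause_in, tuple(config.fc_hidden), dropout_masks)
    return probs, preds, w
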