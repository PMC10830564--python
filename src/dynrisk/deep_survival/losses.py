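"""Composite training loss for the discrete-time survival network.

Three terms: a discrete-time likelihood (event mass at the event bin,
survival mass past the censoring bin), a pairwise ranking term that
pushes events' cumulative incidence above that of subjects still at
risk at the event time, and a step-ahead regression term on the next
exam's observed lab values.  Total = likelihood + alpha * ranking +
beta * prediction.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .grid import TimeGrid

EPS = 1e-8


def loss_likelihood(probs, time, event, grid: TimeGrid):
    """Mean negative log-likelihood under the discretized distribution.

    Events in bin k contribute -log p_k; subjects censored in bin k
    contribute -log of the probability mass strictly after bin k
    (including the terminal event-free slot).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if probs.shape[0] != len(time) or len(time) != len(event):
        raise ValueError("probs, time and event must align")
    n_bins = grid.n_bins
    bins = grid.bin_index(time)
    N = probs.shape[0]
    # survival mass past bin k: sum of slots k+1 .. n_bins (terminal is slot n_bins)
    rev = anp.cumsum(probs[:, ::-1], axis=1)[:, ::-1]  # rev[:, j] = sum of slots >= j
    surv_mass = rev[anp.arange(N), bins + 1]
    event_mass = probs[anp.arange(N), bins]
    ll = anp.where(event == 1, anp.log(event_mass + EPS), anp.log(surv_mass + EPS))
    return -anp.mean(ll)


def loss_ranking(probs, time, event, sigma: float, grid: TimeGrid):
    """Mean ranking kernel exp(-(F_i(s_i) - F_j(s_i)) / sigma) over
    acceptable pairs: i an event at s_i, j with outcome time > s_i.
    Returns 0.0 when the batch has no acceptable pairs."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    e_idx = np.flatnonzero(event == 1)
    if len(e_idx) == 0:
        return anp.sum(probs) * 0.0
    cif = anp.cumsum(probs[:, : grid.n_bins], axis=1)  # (N, n_bins)
    b = grid.bin_index(time[e_idx])  # (E,)
    G = cif[:, b]  # (N, E): G[j, k] = F_j(s_{e_k})
    F_event = G[e_idx, np.arange(len(e_idx))]  # (E,)
    acceptable = time[None, :] > time[e_idx][:, None]  # (E, N)
    n_pairs = acceptable.sum()
    if n_pairs == 0:
        return anp.sum(probs) * 0.0
    kernel = anp.exp(-(F_event[:, None] - G.T) / sigma)
    return anp.sum(kernel * acceptable) / n_pairs


def loss_prediction(preds, batch):
    """MSE of step-ahead predictions over observed next-exam values.

    Steps 2..L are scored (prediction made at the previous step);
    single-exam participants contribute nothing.  Returns 0.0 when no
    target is observed.
    """
    mask = batch.next_mask
    n = mask.sum()
    if n == 0:
        return anp.sum(preds) * 0.0
    sq = (preds - batch.next_target) ** 2
    return anp.sum(sq * mask) / n


def composite_loss(probs, preds, batch, time, event, grid: TimeGrid,
                   alpha: float, beta: float, sigma: float):
    total = loss_likelihood(probs, time, event, grid)
    if alpha > 0:
        total = total + alpha * loss_ranking(probs, time, event, sigma, grid)
    if beta > 0 and preds is not None:
        total = total + beta * loss_prediction(preds, batch)
    return total
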