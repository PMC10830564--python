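"""Discrete time grid for the survival network output."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Half-open bins [l, u) covering (0, horizon], plus a terminal
    event-free slot appended by the network output layer.

    Default: 10-year horizon split into 20 half-year bins, balancing
    temporal resolution against per-bin event counts at cohort scale.
    """

    horizon: float = 10.0
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.n_bins < 1:
            raise ValueError("horizon and n_bins must be positive")

    @property
    def width(self) -> float:
        return self.horizon / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_bins + 1)

    def bin_index(self, t) -> np.ndarray:
        """Bin containing time t in (0, horizon]; t == horizon maps to the last bin."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0) or np.any(t > self.horizon):
            raise ValueError("times must lie in (0, horizon]")
        return np.minimum((t / self.width).astype(int), self.n_bins - 1)


def cif_at(probs: np.ndarray, t: float, grid: TimeGrid) -> float:
    """Cumulative incidence at time t from a per-bin probability vector.

    Sums bins fully below t and linearly interpolates inside the bin
    containing t.  ``probs`` has length n_bins + 1 (terminal slot last).
    Non-decreasing in t; at t = horizon equals 1 - terminal mass.
    """
    if not 0 < t <= grid.horizon:
        raise ValueError(f"t must be in (0, {grid.horizon}], got {t}")
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != grid.n_bins + 1:
        raise ValueError("probability vector length must be n_bins + 1")
    w = grid.width
    full = int(t // w)
    frac = (t - full * w) / w
    head = probs[..., :full].sum(axis=-1)
    if full < grid.n_bins:
        head = head + frac * probs[..., full]
    return head
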