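"""Spatio-temporal correlation filter (STCF) for event denoising.

An event passes the filter only if the total event count in its 3x3 spatial
neighborhood (both polarities, center included, zero padding at the borders)
within the temporal window reaches the spike threshold ``n``.  Real moving
edges are spatially correlated and pass; isolated background-activity noise
events are rejected.  ``n`` is a trainable parameter: during training it is
relaxed to a real value fed through the surrogate-gradient spike function and
rounded at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventGrid

__all__ = ["StcfConfig", "stcf_filter", "neighborhood_sum"]


@dataclass
class StcfConfig:
    """``n``: spike threshold (count); ``window``: temporal window (ms)."""

    n: float = 0.0
    window: float | None = None  # None -> current bin only

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")


def neighborhood_sum(counts: np.ndarray) -> np.ndarray:
    """3x3 neighborhood event sum over both polarities, center included.

    ``counts``: (T, 2, H, W) -> (T, H, W), zero-padded borders.
    """
    tot = counts.sum(axis=1).astype(np.float64)  # (T, H, W)
    p = np.pad(tot, ((0, 0), (1, 1), (1, 1)))
    out = np.zeros_like(tot)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out += p[:, 1 + dy : p.shape[1] - 1 + dy, 1 + dx : p.shape[2] - 1 + dx]
    return out


def stcf_filter(grid: EventGrid, cfg: StcfConfig) -> EventGrid:
    """Filter an event grid; output is binary occupancy per polarity.

    A pixel retains its event iff an input event is present there AND the
    neighborhood sum within the window reaches ``ceil(n)``.  With
    ``window > dt`` the neighborhood sum is a rolling sum over
    ``ceil(window/dt)`` bins ending at the current bin.
    """
    v = neighborhood_sum(grid.counts)
    if cfg.window is not None:
        if cfg.window < grid.dt:
            raise ValueError("window must be >= bin width")
        k = int(np.ceil(cfg.window / grid.dt))
        if k > 1:
            c = np.cumsum(v, axis=0)
            roll = c.copy()
            roll[k:] = c[k:] - c[:-k]
            v = roll
    n_eff = np.ceil(cfg.n)
    passes = v >= n_eff  # (T, H, W)
    out = (grid.counts > 0) & passes[:, None]
    return EventGrid(out.astype(np.int64), dt=grid.dt)
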