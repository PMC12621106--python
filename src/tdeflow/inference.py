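"""Velocity decoding from TDE spike trains.

Two decoders are provided, both gated by *motion segmentation*: a strict
increase of the detector current marks the passage of a new edge (the current
only rises when the trigger fires on available gain), and spikes are
attributed to the most recent such onset.

* spike count — the number of output spikes in a bounded window after the
  onset, scaled linearly (wide range) or affinely with a bias (narrow range);
* inter-spike interval (ISI) — the interval between the first two post-onset
  spikes, recovered by inverting an exponentially decaying spike trace
  ``x[t] = lambda * x[t-1] + s[t]`` with ``lambda = exp(-1/tau_f)``; reading
  the trace at the timestep preceding the second spike gives the elapsed time
  ``t = tau_f * ln(x0/x)`` exactly, hence ``ISI = t + 1`` and the velocity
  estimate ``gamma / ISI``.

Estimates are reported at onset timesteps and are zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRecord", "InferenceConfig", "VelocitySeries",
           "segment_onsets", "spike_count_velocity", "isi_velocity", "decode"]


@dataclass
class SpikeRecord:
    """Binary output spikes and the current trace of one or more detectors.

    Arrays have shape (T,) or (T, ...) with leading time axis.
    """

    spikes: np.ndarray
    current: np.ndarray

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes, dtype=np.float64)
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.spikes.shape != self.current.shape:
            raise ValueError("spikes and current must be aligned")


@dataclass
class InferenceConfig:
    """Decoder settings.

    mode          'count' or 'isi'
    win           spike-count window length, timesteps
    beta          count -> velocity scale (px/timestep per spike), wide range
    bias          px/timestep added when count >= 1 (narrow range); None = wide
    resolution    px/timestep per spike in narrow (bias) mode
    tau_f         spike-trace time constant, timesteps
    gamma         ISI -> velocity scale; estimate = gamma / ISI (wide range)
    v_min, v_max  narrow-range ISI mapping: v = v_min + (v_max - v_min)/ISI
    isi_fallback  ISI used when fewer than 2 spikes follow an onset
    """

    mode: str = "count"
    win: int = 10
    beta: float = 0.1
    bias: float | None = None
    resolution: float = 0.001
    tau_f: float = 5.0
    gamma: float = 1.0
    v_min: float | None = None
    v_max: float | None = None
    isi_fallback: float = 1e4

    def __post_init__(self):
        if self.mode not in ("count", "isi"):
            raise ValueError("mode must be 'count' or 'isi'")
        if self.win < 1:
            raise ValueError("win must be >= 1")
        if self.tau_f <= 0:
            raise ValueError("tau_f must be positive")
        if not 1e3 <= self.isi_fallback <= 1e6:
            raise ValueError("isi_fallback must lie in [1e3, 1e6]")


@dataclass
class VelocitySeries:
    """Per-detector, per-timestep velocity estimates (px/timestep).

    ``estimates`` is zero except at onset timesteps; ``onsets`` is the binary
    segmentation marker series.
    """

    estimates: np.ndarray
    onsets: np.ndarray


def segment_onsets(current: np.ndarray) -> np.ndarray:
    """Mark timesteps where the detector current strictly increases.

    ``current[-1]`` is taken as 0, so a rise at t = 0 counts.  A current
    increase is always the consequence of a trigger activation, hence marks
    the passage of a new edge.
    """
    current = np.asarray(current, dtype=np.float64)
    prev = np.concatenate([np.zeros((1,) + current.shape[1:]), current[:-1]], axis=0)
    return (current > prev).astype(np.float64)


def _segments(onset_idx: np.ndarray, T: int):
    """Half-open [start, next-onset-or-T) segments for each onset."""
    for j, t0 in enumerate(onset_idx):
        t1 = onset_idx[j + 1] if j + 1 < len(onset_idx) else T
        yield int(t0), int(t1)


def spike_count_velocity(rec: SpikeRecord, cfg: InferenceConfig) -> VelocitySeries:
    """Decode velocity from the post-onset spike count (1D record).

    For each onset at t0 the spikes in ``[t0, t0 + win - 1]`` are counted; a
    new onset inside the window restarts counting for the new edge (spikes are
    partitioned among onsets).  Wide range: estimate = beta * count.  Narrow
    range (``bias`` set): estimate = bias + resolution * count for count >= 1.
    """
    if cfg.mode != "count":
        raise ValueError("config mode is not 'count'")
    spikes, current = np.atleast_1d(rec.spikes), np.atleast_1d(rec.current)
    T = spikes.shape[0]
    onsets = segment_onsets(current)
    est = np.zeros(T)
    for t0, t1 in _segments(np.flatnonzero(onsets), T):
        count = spikes[t0 : min(t0 + cfg.win, t1)].sum()
        if cfg.bias is not None:
            est[t0] = cfg.bias + cfg.resolution * count if count >= 1 else 0.0
        else:
            est[t0] = cfg.beta * count
    return VelocitySeries(estimates=est, onsets=onsets)


def isi_velocity(rec: SpikeRecord, cfg: InferenceConfig) -> VelocitySeries:
    """Decode velocity from the interval between the first two post-onset
    spikes, recovered from a low-pass spike trace (1D record).

    The trace is reset at every onset so that its amplitude reflects only the
    current edge.  With fewer than two post-onset spikes the ISI falls back to
    ``cfg.isi_fallback`` (estimate ~ 0 in wide mode, gated to 0 in narrow
    mode).
    """
    if cfg.mode != "isi":
        raise ValueError("config mode is not 'isi'")
    spikes, current = np.atleast_1d(rec.spikes), np.atleast_1d(rec.current)
    T = spikes.shape[0]
    onsets = segment_onsets(current)
    lam = np.exp(-1.0 / cfg.tau_f)

    # trace with reset at onsets
    x = np.zeros(T)
    acc = 0.0
    for t in range(T):
        if onsets[t]:
            acc = 0.0
        acc = lam * acc + spikes[t]
        x[t] = acc

    est = np.zeros(T)
    for t0, t1 in _segments(np.flatnonzero(onsets), T):
        seg_spikes = np.flatnonzero(spikes[t0:t1]) + t0
        if len(seg_spikes) >= 2:
            s1, s2 = seg_spikes[0], seg_spikes[1]
            x0 = x[s1]
            xr = x[s2 - 1]  # trace at the timestep preceding the second spike
            if xr <= 0:
                raise FloatingPointError("non-positive trace at readout")
            isi = cfg.tau_f * np.log(x0 / xr) + 1.0
        else:
            isi = cfg.isi_fallback
        if cfg.v_min is not None and cfg.v_max is not None:
            est[t0] = 0.0 if len(seg_spikes) < 2 else cfg.v_min + (cfg.v_max - cfg.v_min) / isi
        else:
            est[t0] = cfg.gamma / isi
    return VelocitySeries(estimates=est, onsets=onsets)


def decode(rec: SpikeRecord, cfg: InferenceConfig) -> VelocitySeries:
    """Dispatch on ``cfg.mode``; accepts records of shape (T,) or (T, ...)."""
    fn = spike_count_velocity if cfg.mode == "count" else isi_velocity
    if rec.spikes.ndim == 1:
        return fn(rec, cfg)
    T = rec.spikes.shape[0]
    flat_s = rec.spikes.reshape(T, -1)
    flat_i = rec.current.reshape(T, -1)
    est = np.zeros_like(flat_s)
    ons = np.zeros_like(flat_s)
    for d in range(flat_s.shape[1]):
        vs = fn(SpikeRecord(flat_s[:, d], flat_i[:, d]), cfg)
        est[:, d] = vs.estimates
        ons[:, d] = vs.onsets
    return VelocitySeries(
        estimates=est.reshape(rec.spikes.shape), onsets=ons.reshape(rec.spikes.shape)
    )
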