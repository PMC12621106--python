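"""Discrete-time TDE-2 / TDE-3 detector dynamics.

A time-difference encoder converts the delay between activation of spatially
offset inputs into an output spike train.  An event at the *facilitator*
charges a decaying gain ``g``; an event at the *trigger* converts the current
gain into an injected current ``i`` feeding a current-based leaky
integrate-and-fire (CuBa LIF) membrane ``v`` that spikes at threshold and
resets to zero.  TDE-3 adds an *inhibitor* input on the far side of the
trigger that multiplicatively resets the gain, which removes the residual
gain left by motion in the null or orthogonal direction and makes the
detector's direction selectivity structural.

Per-timestep update order (trigger reads the *previous* gain, so a
simultaneous facilitator+trigger injects nothing):

    i[t] = a_i * i[t-1] + g[t-1] * Tr[t]
    g[t] = (a_g * g[t-1] + w_g * Fac[t]) * (1 - Inh[t])      # (1-Inh) TDE-3 only
    v[t] = a_v * v[t-1] + i[t]
    s[t] = H(v[t] - theta);  v[t] <- (1 - s[t]) * v[t]

Decay factors are the per-step retention a = tau/(tau+dt) = sigmoid(p),
parametrized by the unconstrained reals (p_g, p_i, p_v) during training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .inference import SpikeRecord

__all__ = ["TDEParams", "TDEState", "DetectorLayout", "spike_fn", "surrogate_grad",
           "tde_step", "run_tde", "run_tde_network", "DIRECTION_CHANNELS"]

#: channel name -> unit step (dy, dx) from facilitator toward trigger.
DIRECTION_CHANNELS = {
    "L-R": (0, 1),
    "R-L": (0, -1),
    "T-B": (1, 0),
    "B-T": (-1, 0),
}


def _alpha_to_p(alpha: float) -> float:
    return float(np.log(alpha / (1.0 - alpha)))


@dataclass
class TDEParams:
    """Trainable detector parameters.

    ``p_g, p_i, p_v`` are unconstrained; the per-step retention factors are
    ``alpha = sigmoid(p)`` which corresponds to a time constant
    ``tau = dt * alpha / (1 - alpha)``.
    """

    p_g: float
    p_i: float
    p_v: float
    w_g: float = 1.0
    theta: float = 1.0
    dt: float = 10.0  # ms

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.w_g < 0:
            raise ValueError("w_g must be non-negative")

    @classmethod
    def from_time_constants(cls, tau_g, tau_i, tau_v, w_g=1.0, theta=1.0, dt=10.0):
        """Build from time constants in ms (same units as ``dt``)."""
        a = lambda tau: tau / (tau + dt)
        return cls(
            p_g=_alpha_to_p(a(tau_g)),
            p_i=_alpha_to_p(a(tau_i)),
            p_v=_alpha_to_p(a(tau_v)),
            w_g=w_g,
            theta=theta,
            dt=dt,
        )

    @property
    def alpha_g(self):
        return 1.0 / (1.0 + np.exp(-self.p_g))

    @property
    def alpha_i(self):
        return 1.0 / (1.0 + np.exp(-self.p_i))

    @property
    def alpha_v(self):
        return 1.0 / (1.0 + np.exp(-self.p_v))

    def time_constants(self):
        """(tau_g, tau_i, tau_v) in ms."""
        tau = lambda a: self.dt * a / (1.0 - a)
        return tau(self.alpha_g), tau(self.alpha_i), tau(self.alpha_v)


@dataclass
class TDEState:
    """Dynamical state of one (or a batch of) detector(s)."""

    g: np.ndarray | float = 0.0
    i: np.ndarray | float = 0.0
    v: np.ndarray | float = 0.0


@dataclass
class DetectorLayout:
    """Placement of detectors on a pixel grid.

    Detectors are indexed by their trigger pixel; the facilitator sits
    ``spacing`` px against the preferred direction and (TDE-3) the inhibitor
    ``spacing`` px along it, so all three compartments are collinear.
    """

    height: int
    width: int
    spacing: int | np.ndarray = 1
    variant: str = "TDE3"
    channels: tuple = ("L-R", "R-L", "T-B", "B-T")

    def __post_init__(self):
        if self.variant not in ("TDE2", "TDE3"):
            raise ValueError("variant must be TDE2 or TDE3")
        if np.any(np.asarray(self.spacing) < 1):
            raise ValueError("spacing must be >= 1 px")
        for c in self.channels:
            if c not in DIRECTION_CHANNELS:
                raise ValueError(f"unknown channel {c!r}")


def spike_fn(x):
    """Heaviside spike function: 1 where x >= 0 (threshold-inclusive)."""
    return (np.asarray(x) >= 0).astype(np.float64)


def surrogate_grad(x, beta: float = 10.0):
    """Surrogate derivative used in the backward pass: 1/(1 + beta*|x|)^2."""
    return 1.0 / (1.0 + beta * np.abs(np.asarray(x))) ** 2


def tde_step(state: TDEState, fac, tr, inh, params: TDEParams, variant: str = "TDE3"):
    """One timestep of Algorithm-order TDE dynamics.

    Returns ``(new_state, spike)``.  ``inh`` is ignored for TDE-2.  Inputs may
    be scalars or arrays (batched detectors).
    """
    a_g, a_i, a_v = params.alpha_g, params.alpha_i, params.alpha_v
    i_new = a_i * state.i + state.g * tr
    g_new = a_g * state.g + params.w_g * fac
    if variant == "TDE3":
        g_new = g_new * (1.0 - inh)
    v_new = a_v * state.v + i_new
    s = spike_fn(v_new - params.theta)
    v_new = (1.0 - s) * v_new
    return TDEState(g=g_new, i=i_new, v=v_new), s


def run_tde(fac, tr, inh, params: TDEParams, variant: str = "TDE3"):
    """Run detector dynamics over full input sequences.

    ``fac, tr, inh``: binary arrays of shape (T,) or (T, ...) for a batch of
    detectors sharing parameters.  Returns a :class:`SpikeRecord` with spikes
    and the current trace (both same shape as the input).
    """
    fac = np.asarray(fac, dtype=np.float64)
    tr = np.asarray(tr, dtype=np.float64)
    inh = np.zeros_like(fac) if inh is None else np.asarray(inh, dtype=np.float64)
    T = fac.shape[0]
    state = TDEState(
        g=np.zeros(fac.shape[1:]), i=np.zeros(fac.shape[1:]), v=np.zeros(fac.shape[1:])
    )
    spikes = np.zeros_like(fac)
    current = np.zeros_like(fac)
    for t in range(T):
        state, s = tde_step(state, fac[t], tr[t], inh[t], params, variant)
        spikes[t] = s
        current[t] = state.i
    return SpikeRecord(spikes=spikes, current=current)


def _shift2d(occ: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift (T, H, W) occupancy so that output[., y, x] = occ[., y+dy, x+dx],
    zero-padded at the borders."""
    T, H, W = occ.shape
    out = np.zeros_like(occ)
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    yd = slice(max(-dy, 0), H + min(-dy, 0))
    xd = slice(max(-dx, 0), W + min(-dx, 0))
    out[:, yd, xd] = occ[:, ys, xs]
    return out


def run_tde_network(grid, layout: DetectorLayout, params: TDEParams) -> dict:
    """Apply a grid of direction-tuned detectors to an event grid.

    ON and OFF polarities are merged (logical OR per pixel-bin) before the
    detectors.  Every pixel hosts one detector per channel; compartments are
    gathered by strided shifts of the occupancy grid (kernel 3, stride 1 at
    the pixel's spacing).  Returns ``{channel: SpikeRecord}`` with arrays of
    shape (T, H, W).
    """
    occ = grid.occupancy()
    T, H, W = occ.shape
    if H != layout.height or W != layout.width:
        raise ValueError("layout/grid shape mismatch")
    spacing = np.broadcast_to(np.asarray(layout.spacing), (H, W))
    smax = int(spacing.max())
    if 2 * smax >= max(H, W):
        raise ValueError("spacing too large for the field of view")
    yy, xx = np.mgrid[0:H, 0:W]
    out = {}
    for ch in layout.channels:
        dy, dx = DIRECTION_CHANNELS[ch]
        fac = np.zeros_like(occ)
        inh = np.zeros_like(occ)
        for s in np.unique(spacing):
            m = spacing == s
            fac[:, m] = _shift2d(occ, -dy * int(s), -dx * int(s))[:, m]
            inh[:, m] = _shift2d(occ, dy * int(s), dx * int(s))[:, m]
        rec = run_tde(fac, occ, inh, params, layout.variant)
        # disable detectors whose facilitator (or, for TDE-3, inhibitor)
        # would sit outside the field: a border TDE-3 without its inhibitor
        # would silently degrade to a TDE-2
        fy, fx = yy - dy * spacing, xx - dx * spacing
        valid = (fy >= 0) & (fy < H) & (fx >= 0) & (fx < W)
        if layout.variant == "TDE3":
            iy, ix = yy + dy * spacing, xx + dx * spacing
            valid &= (iy >= 0) & (iy < H) & (ix >= 0) & (ix < W)
        rec.spikes *= valid
        rec.current *= valid
        out[ch] = rec
    return out
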