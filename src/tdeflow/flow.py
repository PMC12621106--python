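"""Optical-flow and ego-motion decoding from direction-channel TDE populations.

Each pixel hosts four direction-tuned detectors (L-R, R-L, T-B, B-T).  Since
a point cannot move in two opposite directions at once, opposing channels are
subtracted to give signed flow components; the compartment spacing converts a
per-detector estimate (a fraction of the compartment distance covered per
timestep) into px/s.  The *eccentric* layout grows the spacing with distance
from the image center — a detector with spacing n encodes n-fold higher
velocities without retraining — so a small spacing set covers a wide
dynamic range of retinal speeds.  Yaw ego-rotation is estimated by pooling
L-R spikes with positive and R-L spikes with negative sign.
"""

from __future__ import annotations

import numpy as np

from .inference import InferenceConfig, decode
from .tde import DetectorLayout, TDEParams, run_tde_network

__all__ = [
    "build_eccentric_layout",
    "decode_flow",
    "estimate_yaw_rate",
    "flow_to_rgb",
    "flow_field",
]

ECCENTRIC_SPACINGS = (1, 2, 3, 4, 6, 8)


def build_eccentric_layout(
    height: int,
    width: int,
    spacings=ECCENTRIC_SPACINGS,
    variant: str = "TDE3",
) -> tuple[DetectorLayout, np.ndarray]:
    """Assign compartment spacings on concentric annuli of equal radial
    extent, smallest spacing at the image center.

    Returns the layout and the (H, W) spacing map.
    """
    spacings = np.asarray(sorted(spacings))
    if np.any(np.diff(spacings) <= 0):
        raise ValueError("spacings must be strictly ascending")
    if 2 * spacings.max() >= max(height, width):
        raise ValueError("largest spacing exceeds half the field")
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    edges = np.linspace(0.0, r.max() + 1e-9, len(spacings) + 1)
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(spacings) - 1)
    spacing_map = spacings[idx]
    layout = DetectorLayout(height=height, width=width, spacing=spacing_map,
                            variant=variant)
    return layout, spacing_map


def decode_flow(velocity_by_channel: dict, spacing, dt: float) -> np.ndarray:
    """Combine per-channel velocity estimates into signed flow (px/s).

    ``velocity_by_channel``: {'L-R': (T, H, W), 'R-L': ..., 'T-B': ...,
    'B-T': ...} in px/timestep (fractions of the compartment distance).
    v_x = est(L-R) - est(R-L), v_y = est(T-B) - est(B-T), each scaled by
    spacing * 1000 / dt[ms].  Returns (T, H, W, 2).
    """
    lr = velocity_by_channel["L-R"]
    rl = velocity_by_channel["R-L"]
    tb = velocity_by_channel.get("T-B", np.zeros_like(lr))
    bt = velocity_by_channel.get("B-T", np.zeros_like(lr))
    scale = np.asarray(spacing) * 1000.0 / dt
    vx = (lr - rl) * scale
    vy = (tb - bt) * scale
    return np.stack([vx, vy], axis=-1)


def flow_field(grid, layout: DetectorLayout, params: TDEParams,
               icfg: InferenceConfig) -> np.ndarray:
    """Full pipeline: event grid -> 4-channel detectors -> decoded signed
    flow (T, H, W, 2) in px/s, reported at onset timesteps."""
    recs = run_tde_network(grid, layout, params)
    est = {}
    for ch, rec in recs.items():
        est[ch] = decode(rec, icfg).estimates
    return decode_flow(est, layout.spacing, grid.dt)


def estimate_yaw_rate(spikes_lr: np.ndarray, spikes_rl: np.ndarray,
                      gt_max: float) -> dict:
    """Yaw-rate series from opposing horizontal channels.

    ``spikes_lr/rl``: per-frame spike counts (summed over the field),
    shape (T,).  raw = LR - RL; the frame of maximal |raw| is scaled to the
    caller-provided maximal angular velocity ``gt_max`` (deg/s).  An all-zero
    raw series maps to all-zero output.
    """
    raw = np.asarray(spikes_lr, dtype=np.float64) - np.asarray(spikes_rl, dtype=np.float64)
    peak = np.abs(raw).max()
    scaled = raw * (gt_max / peak) if peak > 0 else np.zeros_like(raw)
    return {"raw": raw, "deg_per_s": scaled}


def flow_to_rgb(flow: np.ndarray) -> np.ndarray:
    """Color-code a flow frame: hue = direction, brightness = magnitude
    normalized by the frame maximum.  ``flow``: (H, W, 2) -> (H, W, 3) RGB
    in [0, 1]; zero flow maps to black."""
    from matplotlib.colors import hsv_to_rgb

    flow = np.asarray(flow, dtype=np.float64)
    mag = np.linalg.norm(flow, axis=-1)
    ang = np.arctan2(flow[..., 1], flow[..., 0])  # (-pi, pi]
    hue = (ang % (2 * np.pi)) / (2 * np.pi)
    peak = mag.max()
    val = mag / peak if peak > 0 else np.zeros_like(mag)
    hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
    return hsv_to_rgb(hsv)
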