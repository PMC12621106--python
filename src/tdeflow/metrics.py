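"""Evaluation metrics for motion detection, optical flow and ego-rotation.

Covers the direction-selectivity index (DSI), the fraction of true activity
(FTA), flow-field errors (average angular error AAE, average endpoint error
AEE and its ground-truth-normalized variant rAEE), yaw-rate errors (mean AVE,
Pearson correlation, average relative rotation error ARRE), and the
IMU-derived ground-truth displacement transform used to build reference flow
for camera-rotation sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import logm

__all__ = [
    "DirectionSpikeCounts",
    "CameraRotationRates",
    "RotationComparison",
    "dsi",
    "fta",
    "flow_errors",
    "rotation_errors",
    "imu_flow_ground_truth",
]


@dataclass
class DirectionSpikeCounts:
    """Spikes fired by one detector during PD, ND and the two OD motions."""

    pd: float
    nd: float = 0.0
    od1: float = 0.0
    od2: float = 0.0

    def __post_init__(self):
        if min(self.pd, self.nd, self.od1, self.od2) < 0:
            raise ValueError("spike counts must be non-negative")

    @property
    def total(self):
        return self.pd + self.nd + self.od1 + self.od2


@dataclass
class CameraRotationRates:
    """IMU rotation rates (deg per frame): x = pitch, y = yaw, z = roll.

    ``k`` converts degrees to pixels for pitch/yaw translation (4.25 px/deg
    for the DAVIS 240C recordings this transform models); ``e0`` is the pixel
    position of the IMU center.
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    e0: tuple = (0.0, 0.0)
    k: float = 4.25

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class RotationComparison:
    """Aligned ground-truth and estimated yaw-rate series (deg/s)."""

    yaw_gt: np.ndarray
    yaw_est: np.ndarray
    dt_s: float = 0.05  # integration interval (s)

    def __post_init__(self):
        self.yaw_gt = np.asarray(self.yaw_gt, dtype=np.float64)
        self.yaw_est = np.asarray(self.yaw_est, dtype=np.float64)
        if self.yaw_gt.shape != self.yaw_est.shape:
            raise ValueError("series must be aligned")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


def dsi(counts: DirectionSpikeCounts) -> float:
    """Direction-selectivity index: PD spikes / total spikes, in [0, 1]."""
    if counts.total <= 0:
        raise ValueError("DSI undefined for zero total spikes")
    return counts.pd / counts.total


def fta(estimates: np.ndarray, attributed: np.ndarray) -> float:
    """Fraction of true activity: stimulus-attributed estimate mass over the
    total estimate mass.

    ``attributed`` is a binary mask marking the timesteps whose estimates are
    caused by the true stimulus (onset within +/-1 timestep of a true edge
    appearance).  A detector with no output at all produced no false
    activity; that case returns 1 by convention.
    """
    estimates = np.asarray(estimates, dtype=np.float64)
    attributed = np.asarray(attributed, dtype=bool)
    total = estimates.sum()
    if total == 0:
        return 1.0
    return float(estimates[attributed].sum() / total)


def flow_errors(v: np.ndarray, u: np.ndarray) -> dict:
    """AAE (deg), AEE and rAEE between estimated flow ``v`` and ground truth
    ``u`` (arrays (..., 2), same units).

    The angular error averages ``arccos`` of the normalized inner product
    over estimates where both vectors are nonzero (zero velocity measurements
    are not counted); the endpoint errors average over all nonzero ground
    truth.
    """
    v = np.asarray(v, dtype=np.float64).reshape(-1, 2)
    u = np.asarray(u, dtype=np.float64).reshape(-1, 2)
    if v.shape != u.shape:
        raise ValueError("flow fields must be aligned")
    nv = np.linalg.norm(v, axis=1)
    nu = np.linalg.norm(u, axis=1)
    both = (nv > 0) & (nu > 0)
    if both.any():
        cosang = (v[both] * u[both]).sum(axis=1) / (nv[both] * nu[both])
        aae = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))).mean())
    else:
        aae = np.nan
    nz = nu > 0
    ee = np.linalg.norm(v - u, axis=1)
    aee = float(ee[nz].mean()) if nz.any() else np.nan
    raee = float((ee[nz] / nu[nz]).mean()) if nz.any() else np.nan
    return {"aae": aae, "aee": aee, "raee": raee}


def _yaw_matrix(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_errors(cmp: RotationComparison, use_matrices: bool = False) -> dict:
    """Mean AVE (deg/s), Pearson r, and yaw ARRE (rad).

    ARRE is the average rotation angle of ``P_t^T G_t`` where P and G are the
    orientations obtained by integrating the estimated and true yaw rates
    over ``dt_s``.  For yaw-only motion this reduces to ``AVE * dt`` after
    degree-to-radian conversion; ``use_matrices=True`` evaluates the full
    matrix-logarithm form instead of the shortcut.
    """
    err = np.abs(cmp.yaw_gt - cmp.yaw_est)
    ave = float(err.mean())
    if cmp.yaw_gt.std() > 0 and cmp.yaw_est.std() > 0:
        corr = float(np.corrcoef(cmp.yaw_gt, cmp.yaw_est)[0, 1])
    else:
        corr = np.nan
    if use_matrices:
        angles = []
        for g, e in zip(cmp.yaw_gt, cmp.yaw_est):
            P = _yaw_matrix(np.radians(e * cmp.dt_s))
            G = _yaw_matrix(np.radians(g * cmp.dt_s))
            L = logm(P.T @ G)
            # rotation angle = ||log(R)||_F / sqrt(2)
            angles.append(np.linalg.norm(np.real(L)) / np.sqrt(2.0))
        arre = float(np.mean(angles))
    else:
        arre = float(np.radians(ave * cmp.dt_s))
    return {"mean_ave": ave, "correlation": corr, "arre_yaw": arre}


def imu_flow_ground_truth(points: np.ndarray, rates: CameraRotationRates) -> np.ndarray:
    """Displace pixel positions according to IMU rotation rates.

    ``e' = R (e - e0 + T) + e0`` with translation ``T = k * (y, x)`` (yaw
    shifts horizontally, pitch vertically) and in-plane rotation ``R`` by the
    roll rate ``z`` about the IMU center ``e0``.  ``points``: (..., 2) as
    (x, y); returns the displaced points with the same shape.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    e0 = np.asarray(rates.e0, dtype=np.float64)
    T = rates.k * np.array([rates.y, rates.x])
    z = np.radians(rates.z)
    R = np.array([[np.cos(z), -np.sin(z)], [np.sin(z), np.cos(z)]])
    out = (R @ (pts - e0 + T).T).T + e0
    return out.reshape(np.asarray(points, dtype=np.float64).shape)
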