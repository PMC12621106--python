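"""Event-file readers/writers and configuration loading.

Event files are either CSV with header ``x,y,t_us,polarity`` or NPZ bundles
with the same four arrays: 0-based integer pixel coordinates, integer
microsecond timestamps, polarity +1 (ON) / -1 (OFF).  Binning to an
:class:`~tdeflow.events.EventGrid` uses half-open bins
``[k*dt, (k+1)*dt)`` with ``floor(t/dt)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EventGrid

__all__ = ["load_events", "save_events", "events_to_grid", "grid_to_events",
           "load_config"]

_COLUMNS = ["x", "y", "t_us", "polarity"]


def events_to_grid(x, y, t_us, polarity, shape: tuple[int, int],
                   dt: float = 10.0, n_bins: int | None = None) -> EventGrid:
    """Bin event records into an EventGrid of spatial ``shape`` (H, W)."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    t_us = np.asarray(t_us, dtype=np.int64)
    polarity = np.asarray(polarity, dtype=np.int64)
    H, W = shape
    if np.any(t_us < 0):
        raise ValueError("negative timestamps")
    if np.any(~np.isin(polarity, (1, -1))):
        bad = np.flatnonzero(~np.isin(polarity, (1, -1)))[0]
        raise ValueError(f"unknown polarity value at record {bad}")
    if np.any((x < 0) | (x >= W) | (y < 0) | (y >= H)):
        bad = np.flatnonzero((x < 0) | (x >= W) | (y < 0) | (y >= H))[0]
        raise ValueError(f"out-of-bounds coordinates at record {bad}")
    bins = (t_us // int(dt * 1000)).astype(np.int64)
    if n_bins is None:
        n_bins = int(bins.max()) + 1 if bins.size else 1
    counts = np.zeros((n_bins, 2, H, W), dtype=np.int64)
    pol_idx = (polarity < 0).astype(np.int64)  # 0 = ON, 1 = OFF
    np.add.at(counts, (bins, pol_idx, y, x), 1)
    return EventGrid(counts, dt=dt)


def grid_to_events(grid: EventGrid) -> dict:
    """Expand an EventGrid into sorted event records (timestamps at bin
    starts, so a round trip through :func:`events_to_grid` is the identity
    on the binned representation)."""
    t_bin, pol_idx, y, x = np.nonzero(grid.counts)
    reps = grid.counts[t_bin, pol_idx, y, x]
    t_us = np.repeat(t_bin, reps) * int(grid.dt * 1000)
    x = np.repeat(x, reps)
    y = np.repeat(y, reps)
    polarity = np.where(np.repeat(pol_idx, reps) == 0, 1, -1)
    order = np.argsort(t_us, kind="stable")
    return {"x": x[order], "y": y[order], "t_us": t_us[order],
            "polarity": polarity[order]}


def save_events(grid: EventGrid, path) -> None:
    """Write an EventGrid to ``.csv`` or ``.npz`` (by file extension).

    The spatial shape and bin width are stored alongside (NPZ keys, or a
    ``# shape=HxW dt=...`` comment line in CSV) so the grid round-trips.
    """
    path = Path(path)
    ev = grid_to_events(grid)
    T, _, H, W = grid.shape
    if path.suffix == ".npz":
        np.savez(path, shape=np.array([T, H, W]), dt=np.array([grid.dt]), **ev)
    elif path.suffix == ".csv":
        with open(path, "w") as fh:
            fh.write(f"# shape={T}x{H}x{W} dt={grid.dt}\n")
            pd.DataFrame(ev)[_COLUMNS].to_csv(fh, index=False)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")


def load_events(path, shape: tuple[int, int] | None = None,
                dt: float | None = None, n_bins: int | None = None) -> EventGrid:
    """Read events from ``.csv`` / ``.npz``; ``shape`` (H, W) and ``dt``
    override any stored metadata (required if none is stored)."""
    path = Path(path)
    meta_shape = meta_dt = None
    if path.suffix == ".npz":
        with np.load(path) as z:
            missing = [k for k in _COLUMNS if k not in z]
            if missing:
                raise ValueError(f"NPZ missing arrays: {missing}")
            ev = {k: z[k] for k in _COLUMNS}
            if "shape" in z:
                t, h, w = z["shape"]
                meta_shape, n_bins = (int(h), int(w)), n_bins or int(t)
            if "dt" in z:
                meta_dt = float(z["dt"][0])
    elif path.suffix == ".csv":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("shape="):
                        t, h, w = (int(v) for v in tok[6:].split("x"))
                        meta_shape, n_bins = (h, w), n_bins or t
                    elif tok.startswith("dt="):
                        meta_dt = float(tok[3:])
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed header, missing columns: {missing}")
        ev = {k: df[k].to_numpy() for k in _COLUMNS}
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")
    shape = shape or meta_shape
    dt = dt or meta_dt
    if shape is None or dt is None:
        raise ValueError("spatial shape and dt required (not stored in file)")
    return events_to_grid(ev["x"], ev["y"], ev["t_us"], ev["polarity"],
                          shape=shape, dt=dt, n_bins=n_bins)


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration as a plain nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
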