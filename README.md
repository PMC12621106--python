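# tdeflow

Spiking time-difference-encoder (TDE) motion detection: a complete synthetic
test bench for the three-compartment TDE-3 detector, its two-compartment
predecessor TDE-2, their supervised training with surrogate-gradient BPTT,
and optical-flow / ego-motion decoding from detector populations.

## The problem

Event cameras report asynchronous per-pixel ON/OFF events when log-intensity
changes exceed a contrast threshold.  A time-difference encoder converts the
*delay* between events at spatially offset inputs into an output spike train:
an event at the **facilitator** charges a decaying gain g, a later event at
the **trigger** converts the remaining gain into current driving a
current-based leaky integrate-and-fire membrane,

    i[t] = α_i·i[t-1] + g[t-1]·Tr[t]
    g[t] = (α_g·g[t-1] + w_g·Fac[t])·(1 − Inh[t])
    v[t] = α_v·v[t-1] + i[t],    s[t] = H(v[t] − θ),    v ← (1 − s)·v

so faster motion → shorter delay → more residual gain → more spikes with
shorter inter-spike intervals (ISI).  The classic two-point detector (TDE-2)
loses direction selectivity in textured scenes: null- or orthogonal-direction
motion leaves residual gain that the *next* edge triggers.  The three-point
detector (TDE-3) adds an **inhibitor** input beyond the trigger that resets
the gain — the `(1 − Inh[t])` factor above — making direction selectivity a
structural property rather than a tuning accident.

The package provides:

* `tdeflow.events` — a log-intensity event-camera simulator, moving-edge and
  three-level bar-texture stimuli, Poisson background-activity noise;
* `tdeflow.stcf` — the spatio-temporal correlation filter (denoiser) with a
  trainable pass threshold;
* `tdeflow.tde` — TDE-2/TDE-3 dynamics, batched over pixel grids in four
  direction channels;
* `tdeflow.inference` — velocity decoding by post-onset spike count or by
  exact inversion of a low-pass spike trace (ISI), with trigger-onset motion
  segmentation;
* `tdeflow.training` — BPTT with surrogate gradients for both decoding
  schemes, joint training of the denoiser threshold under noise;
* `tdeflow.flow` / `tdeflow.metrics` — opposing-channel optical flow,
  eccentric compartment spacing, yaw-rate pooling, and the evaluation suite
  (DSI, FTA, AAE/AEE/rAEE, AVE/ARRE, IMU-derived ground-truth flow);
* `tdeflow.experiments` — runnable protocols (randomized direction-
  selectivity study, velocity-mapping benchmarks, noise sweeps).

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Direction selectivity of a single left-right detector under randomly drawn
parameters and random bar textures:

```python
from tdeflow.experiments import run_dsi_experiment

r3 = run_dsi_experiment("TDE3", n_rounds=8, n_stimuli=100, seed=0)
r2 = run_dsi_experiment("TDE2", n_rounds=8, n_stimuli=100, seed=0)
print("TDE-3 DSI per round:", r3["dsi_per_round"])
print("TDE-2 mean DSI: %.3f +/- %.3f" % (r2["mean"], r2["std"]))
```

```
TDE-3 DSI per round: [1. 1. 1. 1. 1. 1. 1. 1.]
TDE-2 mean DSI: 0.256 +/- 0.042
```

Every TDE-3 round has a direction-selectivity index of exactly 1.0 — all
spikes occur during preferred-direction motion, for *any* parameter draw over
a 10-fold range — while the TDE-2 fires for every motion direction and its
DSI sits near chance (0.25 would be fully unselective).

Training a detector to map edge velocity linearly onto its spike count, then
decoding a fresh batch:

```python
from tdeflow.training import EdgeTaskGenerator, TrainConfig, train_tde
from tdeflow.experiments import evaluate_detector

gen = EdgeTaskGenerator("wide", n_edges=1)        # 5 velocities, 0.1-1 px/step
cfg = TrainConfig(mode="count", velocity_set="wide", epochs=600, seed=1)
params, _, hist = train_tde(gen, cfg)
r = evaluate_detector(gen, params, "count", n=150, seed=99)
print("r = %.3f, mean spikes/stimulus = %.2f" % (r["correlation"], r["mean_spikes"]))
```

```
r = 0.928, mean spikes/stimulus = 3.59
```

Decoded velocity correlates strongly with the stimulus velocity while the
detector spends under four spikes per edge; training with ISI decoding
instead (`mode="isi"`, with a few restarts) reaches r ≈ 0.99 at about two
spikes per edge — the latency-friendly, spike-frugal code.

A command-line interface covers the same pipeline:

```sh
tdeflow simulate --stimulus bars --velocity 0.5 --noise-rate 2 --seed 1 --out events.npz
tdeflow train --mode count --range wide --epochs 600 --seed 1 --out params.json
tdeflow flow --events events.npz --params params.json --variant tde3 --out flow.npz
tdeflow dsi --variant tde3 --rounds 40 --stimuli 200 --seed 1 --out dsi.csv
```

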