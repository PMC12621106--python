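# Methods

This note documents the models, algorithms and numerical choices behind
`tdeflow`: what is simulated, how the detectors are trained, and what the
synthetic experiments do and do not establish.

## Event-camera model

Pixel voltage is taken proportional to the logarithm of light intensity.  An
ON (OFF) event is emitted at pixel (x, y) in bin t whenever

    log I_t - log I_{t-1} > +c      (ON),      < -c      (OFF),

with contrast threshold c = 0.15.  The model is memoryless frame differencing:
there is no per-pixel reference level, refractory period, or latency jitter.
Consequently event counts are invariant to a global intensity rescaling, and a
step edge crossing a pixel produces exactly one event of one polarity.

Stimuli are rendered at integer pixel positions by nearest-integer placement
(`floor(x + 0.5)`), so a stimulus moving at v px/timestep advances one pixel
every 1/v timesteps and integer inter-edge distances are preserved exactly
during translation.  The three bar intensities are fixed at black = 0.2,
gray = 0.5, white = 1.0 (arbitrary units); all pairwise log-contrasts
(0.69–1.61) exceed c, so every bar boundary generates events.  Bars are 2 px
wide along the motion axis.  Background-activity noise adds independent
Poisson(rate · dt) events per pixel, polarity and bin, injected *after* event
conversion.

Velocity sets are reciprocals of integer trigger delays: the wide (10-fold)
set is {0.1, 0.2, 1/3, 0.5, 1} px/timestep and the narrow (1.5-fold) set is
{1/39, …, 1/25} ≈ 0.0256–0.04 px/timestep (15 values).  The timestep is
10 ms for the synthetic experiments and 50 ms for the flow/ego-motion
networks.

## Detector dynamics

A TDE is a current-based leaky integrate-and-fire neuron with a gated input.
Per timestep (order matters; the trigger reads the previous gain):

    i[t] = a_i · i[t-1] + g[t-1] · Tr[t]
    g[t] = (a_g · g[t-1] + w_g · Fac[t]) · (1 − Inh[t])   # (1−Inh): TDE-3 only
    v[t] = a_v · v[t-1] + i[t]
    s[t] = H(v[t] − θ);   v[t] ← (1 − s[t]) · v[t]

with θ = 1 and decay (retention) factors a = sigmoid(p) = τ/(τ + dt).  Note
the per-step *retention* convention: long time constants mean a close to 1.
Because the trigger converts the previous step's gain, simultaneous
facilitator+trigger activation injects nothing (orthogonal-direction safety),
and because inhibition multiplies after facilitation, simultaneous
facilitator+inhibitor activation leaves no gain behind.

For a left-to-right tuned detector the facilitator sits one spacing left of
the trigger and (TDE-3) the inhibitor one spacing right.  In the grid runner
every pixel hosts four direction-tuned detectors via strided shifts of the
merged-polarity occupancy; detectors whose facilitator or inhibitor would
fall outside the field are disabled rather than run without that compartment
(a border TDE-3 missing its inhibitor would silently degrade to a TDE-2).

Why TDE-3 direction selectivity is structural: with bars at least 2 px wide
and unit compartment spacing, in null-direction motion every edge that could
trigger the detector has itself crossed the inhibitor no earlier than one
step after any facilitator activation, so the gain is always zero when read;
in orthogonal motion the facilitator and inhibitor fire simultaneously and
the gain never forms.  The randomized-parameter protocol in
`run_dsi_experiment` confirms a DSI of exactly 1 for every parameter draw.

## Noise filtering (STCF)

An event passes the spatio-temporal correlation filter iff the event count in
its 3×3 neighborhood (both polarities, center included, zero padding) within
the temporal window reaches the threshold n; output is binary occupancy per
polarity and always a subset of the (binarized) input.  The window defaults
to the bin width; wider windows use a rolling sum.  During training n is
relaxed to a real value passed through the surrogate spike function and
rounded up at inference.

## Velocity decoding

Motion segmentation: a strict increase of the detector current marks the
passage of a new edge (current only rises when the trigger fires on available
gain).  Spikes are attributed to the most recent onset.

**Spike count.**  Spikes in a window after the onset (10 timesteps for the
wide set and all multi-edge tasks, 40 for the narrow single-edge task, 5 for
the 50 ms flow networks), truncated at the next onset.  Wide mapping:
estimate = 0.1 px/timestep per spike, so one spike encodes the slowest
stimulus.  Narrow mapping: estimate = 0.024 + 0.001·count px/timestep for
count ≥ 1 — the bias lets one spike encode ≈0.025 px/timestep instead of 25.

**Inter-spike interval.**  A low-pass trace x[t] = λ·x[t-1] + s[t] with
λ = exp(−1/τ_f), τ_f = 5 timesteps, reset at each onset so the amplitude
reflects only the current edge.  Reading the trace at the timestep preceding
the second post-onset spike gives the elapsed time exactly:
t = τ_f · ln(x0/x), ISI = t + 1 (an identity for all integer gaps — the
decay is chosen as exp(−1/τ_f) precisely so this inversion is exact).  Wide
mapping: estimate = v_max/ISI, so ISI = 1 maps to the fastest stimulus.
Narrow mapping: estimate = v_min + (v_max − v_min)/ISI.  Fewer than two
post-onset spikes fall back to ISI = 10⁴ (estimate ≈ 0; gated to exactly 0
in narrow mode).

## Training

Trainable parameters: p_g, p_i, p_v (decays through sigmoid), w_g, and in
noisy mode the relaxed STCF threshold n.  θ is fixed at 1.  The loss is

    L = (1/N) Σ_b |v̂_est,b − v̂_true,b|  +  0.05·(10⁻²·(1/N) Σ_b (Σ_t s_b)²)^½

where both velocity vectors are divided by the batch-maximum true velocity.
A *joint* normalizer is deliberate: normalizing estimates and truths by their
own maxima separately makes every proportionally rescaled mapping
est = c·v loss-free, and the sparsity term then shrinks c without bound —
observable as systematically compressed estimates.  The joint normalizer
conditions the loss scale while pinning the absolute mapping.

Estimates are computed per onset; each example's onset terms are averaged,
and a true edge that no onset accounts for contributes its full normalized
velocity (a silent detector does not get a free pass).  In noisy training the
ground truth assigned to an onset is the edge velocity when the onset falls
within ±1 timestep of a true edge appearance at the trigger pixel, and zero
otherwise, so noise-driven activations are actively suppressed; the same
noise rate is used in training and test.

**Differentiation.**  The recurrence is unrolled and differentiated with
BPTT.  The Heaviside threshold uses the surrogate derivative
1/(1 + 10·|x|)² (peaked at threshold, strictly positive) in the backward
pass — for the membrane threshold, the STCF threshold, and every gate in the
decoding head.  Segmentation indices (onset times, first/second spike
positions, count windows) are treated as constants of the backward pass.
For speed the recurrence runs as a plain numpy loop with a hand-derived
backward pass; the decoding head is built on a small reverse-mode tape with
the per-step spikes and currents as leaves.  A tape-only reference
implementation of the recurrence is kept and the two backward passes agree
to machine precision (tested).

Two decoding-head details matter for trainability:

* *ISI readout gradient.*  Between the first and second post-onset spikes
  the trace is spike-free, so x = λ^(k−1)·x0 and ln(x0/x) carries no
  gradient at all — every continuous dependence cancels.  The readout is
  therefore gated by the soft second spike (forward value ×1), which routes
  a correctly signed surrogate gradient through the second spike's membrane
  potential: raising it shortens the ISI and raises the estimate.
* *Revival gradient.*  A segment with fewer than two spikes has a constant
  fallback estimate; to keep silent detectors trainable the zero estimate is
  expressed as H(count − 1.5)·scale, whose surrogate derivative pulls toward
  spiking when the target velocity is nonzero.

**Optimization.**  Adam, lr 10⁻², with a 10× step decay over the last 40% of
epochs; 100 freshly generated examples per epoch (stimuli are regenerated
every epoch, so there is no train/test split to overfit).  Initialization is
a high-firing regime — w_g = 5 and time constants of twice the slowest
stimulus delay (20 timesteps for the wide tasks, ≈80 for the narrow task) —
so surrogate gradients do not vanish at the start.  The returned parameters
are the snapshot with the lowest exponentially smoothed training loss;
single-epoch losses are noisy and the pulsatile ISI objective can wander
late in training.  Epoch budgets used by the acceptance script: 600 (wide
count), 2000 (ISI modes and narrow count 3000) — ISI training converges in
jumps and needs several times more epochs than count training, consistent
with its discrete objective.

## Flow and ego-motion networks

Opposing channels subtract: v_x = est(L-R) − est(R-L), v_y = est(T-B) −
est(B-T), scaled to px/s by spacing·1000/dt.  A detector with compartment
spacing n encodes n-fold higher velocities with unchanged parameters, so the
eccentric layout (spacings {1,2,3,4,6,8} on concentric equal-width annuli,
smallest at the image center) spans 2–80 px/s at dt = 50 ms with per-detector
ranges of 0.1–0.5 px/timestep.  Yaw rate pools L-R spikes positively and R-L
spikes negatively per frame; the caller supplies the maximal angular velocity
to anchor the scale (the raw pooled signal is unitless).  Flow maps are
color-coded with hue = direction, brightness = magnitude/frame-maximum.

Metrics: AAE averages arccos of the normalized inner product over estimates
where both vectors are nonzero; AEE/rAEE average the (ground-truth-
normalized) endpoint error over nonzero ground truth; mean AVE is the mean
absolute yaw-rate difference; ARRE is the mean rotation angle of Pᵗ G per
frame, which for yaw-only motion reduces to AVE·Δt in radians (both forms
implemented; they agree to <10⁻⁶ rad on yaw-only series).  The IMU-derived
ground-truth displacement is e′ = R(e − e₀ + T) + e₀ with T = k·(yaw, pitch),
k = 4.25 px/°, and R the in-plane roll rotation.

## What the synthetic data does and does not show

The generator reproduces the structural conditions of the synthetic
experiments: rigid integer-rendered motion, ideal thresholds, simultaneous
events along an edge, and purely Poisson noise.  Real event streams add
per-pixel threshold mismatch, latency jitter (which specifically threatens
the simultaneity that orthogonal-direction suppression relies on — time
binning mitigates but does not remove this), hot pixels, and non-stationary
statistics.  Passing the synthetic suite therefore establishes algorithmic
correctness and trainability, not sensor-level robustness; the real-data
behaviors (rotating-disk flow, driving-sequence yaw) are exercised here only
through synthetic stand-ins at matched bin widths.

## Degenerate inputs and tie-breaks

The spike function fires at exactly threshold (H(0) = 1), consistently for
the membrane, the STCF and the current-increase gate (which requires a
*strict* increase).  DSI is undefined for a round with zero total spikes;
such rounds are excluded and counted.  FTA of an all-zero estimate series is
1 by convention (no false activity).  An all-zero pooled yaw signal returns
an all-zero series rather than dividing by zero.  Empty event files load as
empty grids of the declared shape.

## Problem sizes

The randomized direction-selectivity protocol runs 40 rounds × 200 stimuli
(the package's default desk-scale setting; the protocol is seed-deterministic
at any scale).  Velocity-mapping evaluations use 150 fresh stimuli per
configuration.  Training batches are 100 examples per epoch throughout.
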