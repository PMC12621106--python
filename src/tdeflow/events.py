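"""Synthetic event-camera stimuli: moving edges, three-level bar textures,
log-intensity event conversion, and Poisson background-activity noise.

The camera model is deliberately simple.  Pixel voltage is the logarithm of
light intensity; an ON (OFF) event is emitted whenever the one-frame temporal
derivative ``log I_t - log I_{t-1}`` exceeds ``+threshold`` (falls below
``-threshold``).  There is no per-pixel reference level or refractory period:
the model is memoryless frame differencing.  Sub-pixel stimulus positions are
rendered by nearest-integer placement, so a stimulus translating at a
fractional velocity advances one pixel every ``1/v`` timesteps.

Intensities of the three-level bar textures are fixed at black = 0.2,
gray = 0.5, white = 1.0 (arbitrary units): every pairwise log-contrast
(0.69-1.6) is well above the default event threshold of 0.15, so every bar
boundary produces events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensitySequence",
    "EventGrid",
    "StimulusSpec",
    "INTENSITY_LEVELS",
    "DEFAULT_THRESHOLD",
    "WIDE_VELOCITIES",
    "NARROW_VELOCITIES",
    "EDGE_SPACINGS",
    "simulate_events",
    "make_bar_stimulus",
    "make_edge_stimulus",
    "inject_background_noise",
    "bar_texture",
    "texture_pixel_series",
]

#: black / gray / white light intensities (arbitrary positive units).
INTENSITY_LEVELS = {"black": 0.2, "gray": 0.5, "white": 1.0}

#: Event-camera contrast threshold on the log-intensity derivative.
DEFAULT_THRESHOLD = 0.15

#: Wide (10-fold) velocity set, px/timestep: reciprocal integer delays 1/{10,5,3,2,1}.
WIDE_VELOCITIES = np.array([0.1, 0.2, 1 / 3, 0.5, 1.0])

#: Narrow (1.5-fold) velocity set: v = 1/k for k = 39..25, i.e. 0.0256-0.04 px/timestep.
NARROW_VELOCITIES = 1.0 / np.arange(39, 24, -1)

#: Inter-edge spacings (px) for the two-edge spatial-frequency task.
EDGE_SPACINGS = np.array([3, 4, 5, 7, 10])

DIRECTIONS = ("L-R", "R-L", "T-B", "B-T")


@dataclass
class IntensitySequence:
    """Grayscale frames (T, H, W) in arbitrary positive units plus timestep."""

    frames: np.ndarray
    dt: float = 10.0  # ms

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if np.any(self.frames <= 0):
            raise ValueError("intensities must be positive (log must be defined)")


@dataclass
class EventGrid:
    """Time-binned event counts, shape (T, 2, H, W); polarity axis is (ON, OFF)."""

    counts: np.ndarray
    dt: float = 10.0  # ms

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4 or self.counts.shape[1] != 2:
            raise ValueError("counts must be (T, 2, H, W)")
        if np.any(self.counts < 0):
            raise ValueError("event counts must be non-negative")

    @property
    def shape(self):
        return self.counts.shape

    def occupancy(self) -> np.ndarray:
        """Merged-polarity binary occupancy, shape (T, H, W)."""
        return (self.counts.sum(axis=1) > 0).astype(np.float64)

    def binary(self) -> "EventGrid":
        return EventGrid((self.counts > 0).astype(self.counts.dtype), dt=self.dt)


@dataclass
class StimulusSpec:
    """Parameters of a moving three-level bar texture."""

    velocity: float  # px/timestep, > 0
    direction: str = "L-R"
    gray_fraction: float = 0.0
    texture_length: int = 80  # px along the motion axis
    texture_width: int = 3  # px orthogonal to motion
    bar_width: int = 2  # px per bar along the motion axis
    noise_rate: float = 0.0  # Hz/px
    seed: int = 0

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 <= self.gray_fraction <= 0.8:
            raise ValueError("gray_fraction must lie in [0, 0.8]")


def simulate_events(frames: IntensitySequence, threshold: float = DEFAULT_THRESHOLD) -> EventGrid:
    """Convert an intensity sequence to ON/OFF events by thresholding the
    temporal log-intensity derivative at ``+/-threshold``.

    The first output bin corresponds to the transition into frame 1, so the
    event grid has ``T`` bins for ``T+1`` frames; bin 0 is empty by
    construction (no derivative exists before the first frame).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    f = frames.frames
    if f.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    dlog = np.diff(np.log(f), axis=0)
    T, H, W = f.shape
    counts = np.zeros((T, 2, H, W), dtype=np.int64)
    counts[1:, 0] = dlog > threshold
    counts[1:, 1] = dlog < -threshold
    return EventGrid(counts, dt=frames.dt)


def bar_texture(
    length: int,
    gray_fraction: float,
    rng: np.random.Generator,
    bar_width: int = 2,
) -> np.ndarray:
    """1D intensity profile of a bar texture along the motion axis.

    Bars alternate black/white; each bar is independently replaced by gray
    with probability ``gray_fraction``, so gray bars occupy that fraction in
    expectation.  Returns an array of length ``length`` (px).
    """
    n_bars = int(np.ceil(length / bar_width))
    levels = np.empty(n_bars)
    levels[0::2] = INTENSITY_LEVELS["black"]
    levels[1::2] = INTENSITY_LEVELS["white"]
    gray_mask = rng.random(n_bars) < gray_fraction
    levels[gray_mask] = INTENSITY_LEVELS["gray"]
    return np.repeat(levels, bar_width)[:length]


def texture_pixel_series(
    texture: np.ndarray,
    velocity: float,
    n_steps: int,
    pixel: int,
    start: float,
    background: float = INTENSITY_LEVELS["gray"],
) -> np.ndarray:
    """Intensity time series seen by one pixel as a 1D texture translates
    past it at ``velocity`` px/timestep (nearest-integer placement).

    ``start`` is the position of the texture's leading element at t = 0; the
    texture occupies ``[offset, offset + len)`` at each timestep where
    ``offset = round(start + velocity * t)``.
    """
    t = np.arange(n_steps)
    offset = np.floor(start + velocity * t + 0.5).astype(int)
    idx = pixel - offset
    inside = (idx >= 0) & (idx < len(texture))
    series = np.full(n_steps, background)
    series[inside] = texture[idx[inside]]
    return series


def make_bar_stimulus(
    spec: StimulusSpec,
    field_shape: tuple[int, int],
    n_steps: int | None = None,
    dt: float = 10.0,
) -> IntensitySequence:
    """Render a rigidly translating three-level bar texture into intensity
    frames over a (H, W) field on a uniform gray background.

    Bars are orthogonal to the motion axis.  The texture starts just outside
    the field and crosses it completely when ``n_steps`` is left unset.
    """
    H, W = field_shape
    rng = np.random.default_rng(spec.seed)
    tex = bar_texture(spec.texture_length, spec.gray_fraction, rng, spec.bar_width)
    horizontal = spec.direction in ("L-R", "R-L")
    axis_len = W if horizontal else H
    ortho_len = H if horizontal else W
    if spec.texture_width > ortho_len:
        raise ValueError("texture wider than the field of view")
    travel = axis_len + spec.texture_length
    if n_steps is None:
        n_steps = int(np.ceil(travel / spec.velocity)) + 2

    # signed motion along the axis; texture enters from the near side
    forward = spec.direction in ("L-R", "T-B")
    v = spec.velocity if forward else -spec.velocity
    start = -spec.texture_length if forward else axis_len

    t = np.arange(n_steps)
    offset = np.floor(start + v * t + 0.5).astype(int)  # leading texture element
    frames = np.full((n_steps, H, W), INTENSITY_LEVELS["gray"])
    axis_coords = np.arange(axis_len)
    idx = axis_coords[None, :] - offset[:, None]  # (T, axis_len)
    inside = (idx >= 0) & (idx < spec.texture_length)
    profile = np.full((n_steps, axis_len), INTENSITY_LEVELS["gray"])
    profile[inside] = tex[idx[inside]]

    o0 = (ortho_len - spec.texture_width) // 2
    osl = slice(o0, o0 + spec.texture_width)
    if horizontal:
        frames[:, osl, :] = profile[:, None, :]
    else:
        frames[:, :, osl] = profile[:, :, None]
    return IntensitySequence(frames, dt=dt)


def make_edge_stimulus(
    velocity: float,
    n_edges: int = 1,
    spacings: np.ndarray | None = None,
    seed: int = 0,
    width: int = 16,
    height: int = 1,
    n_steps: int | None = None,
    start: float = 0.5,
    dt: float = 10.0,
) -> tuple[IntensitySequence, np.ndarray]:
    """Step edge(s) on a homogeneous background translating left-to-right.

    The scene is dark behind each edge: pixel x is white while the leading
    edge has not reached it and steps to black once it passes (a second edge
    restores white, giving a dark stripe between the two edges).  Returns the
    intensity sequence and the sampled edge offsets (px, leading edge first).

    For ``n_edges == 2`` the inter-edge distance is drawn uniformly from
    ``spacings`` (default {3, 4, 5, 7, 10} px).
    """
    if n_edges not in (1, 2):
        raise ValueError("n_edges must be 1 or 2")
    rng = np.random.default_rng(seed)
    if n_edges == 2:
        pool = EDGE_SPACINGS if spacings is None else np.asarray(spacings)
        if pool.size == 0:
            raise ValueError("empty spacing set")
        gap = int(rng.choice(pool))
        offsets = np.array([0, gap])
    else:
        offsets = np.array([0])
    travel = width + offsets.max()
    if n_steps is None:
        n_steps = int(np.ceil(travel / velocity)) + 2

    t = np.arange(n_steps)
    lead = np.floor(start + velocity * t + 0.5).astype(int)  # leading edge position
    x = np.arange(width)
    # region between edge j and edge j+1 alternates white/black
    passed = np.zeros((n_steps, width), dtype=int)
    for off in offsets:
        passed += (x[None, :] < (lead[:, None] - off)).astype(int)
    white, black = INTENSITY_LEVELS["white"], INTENSITY_LEVELS["black"]
    frames1d = np.where(passed % 2 == 1, black, white)
    frames = np.broadcast_to(frames1d[:, None, :], (n_steps, height, width)).copy()
    return IntensitySequence(frames, dt=dt), offsets


def inject_background_noise(grid: EventGrid, rate: float, seed: int = 0) -> EventGrid:
    """Add Poisson background-activity events at ``rate`` Hz/px per polarity.

    Each pixel, polarity and time bin independently receives
    ``Poisson(rate * dt / 1000)`` extra events; the original events are
    preserved.  Noise is injected into the binned grid, after event
    conversion.
    """
    if rate < 0:
        raise ValueError("noise rate must be non-negative")
    if rate == 0:
        return grid
    rng = np.random.default_rng(seed)
    lam = rate * grid.dt * 1e-3
    noise = rng.poisson(lam, size=grid.counts.shape)
    return EventGrid(grid.counts + noise, dt=grid.dt)
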