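"""Event-camera simulator: log-contrast thresholding, stimulus rendering,
and Poisson background-activity noise."""

import numpy as np
import pytest

from tdeflow.events import (
    EDGE_SPACINGS,
    NARROW_VELOCITIES,
    StimulusSpec,
    IntensitySequence,
    bar_texture,
    inject_background_noise,
    make_bar_stimulus,
    make_edge_stimulus,
    simulate_events,
)


class TestSimulateEvents:
    def test_constant_frames_produce_no_events(self):
        seq = IntensitySequence(np.full((10, 4, 4), 0.7))
        assert simulate_events(seq).counts.sum() == 0

    def test_single_step_above_threshold_gives_one_on_event(self):
        frames = np.full((3, 2, 2), 1.0)
        frames[1:, 0, 0] *= np.exp(0.2)  # delta log I = +0.2 > 0.15
        grid = simulate_events(IntensitySequence(frames), threshold=0.15)
        assert grid.counts.sum() == 1
        assert grid.counts[1, 0, 0, 0] == 1  # ON polarity, the stepped pixel

    def test_single_step_down_gives_one_off_event(self):
        frames = np.full((3, 2, 2), 1.0)
        frames[1:, 1, 1] *= np.exp(-0.2)
        grid = simulate_events(IntensitySequence(frames), threshold=0.15)
        assert grid.counts.sum() == 1
        assert grid.counts[1, 1, 1, 1] == 1  # OFF polarity

    def test_subthreshold_contrast_is_ignored(self):
        frames = np.full((3, 1, 1), 1.0)
        frames[1:] *= np.exp(0.1)
        assert simulate_events(IntensitySequence(frames)).counts.sum() == 0

    def test_scale_invariance_of_log_contrast(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0.3, 1.0, size=(15, 5, 7))
        g1 = simulate_events(IntensitySequence(frames))
        g2 = simulate_events(IntensitySequence(frames * 37.5))
        np.testing.assert_array_equal(g1.counts, g2.counts)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            IntensitySequence(np.zeros((3, 2, 2)))


class TestEdgeStimulus:
    def test_unit_velocity_edge_advances_one_pixel_per_step(self):
        seq, _ = make_edge_stimulus(1.0, width=10, start=0.0)
        grid = simulate_events(seq)
        occ = grid.occupancy()[:, 0, :]
        cols = [np.flatnonzero(occ[t]) for t in range(1, 10)]
        xs = [c[0] for c in cols if c.size]
        assert xs == sorted(xs)
        assert np.diff(xs).tolist() == [1] * (len(xs) - 1)

    def test_half_velocity_advances_every_other_step(self):
        # nearest-integer placement oracle: positions floor(start + v t + .5)
        seq, _ = make_edge_stimulus(0.5, width=8, start=0.0, n_steps=14)
        grid = simulate_events(seq)
        occ = grid.occupancy()[:, 0, :]
        event_times = np.flatnonzero(occ.any(axis=1))
        assert np.all(np.diff(event_times) == 2)

    def test_single_edge_fires_once_per_pixel(self):
        seq, _ = make_edge_stimulus(0.25, width=6, start=0.0)
        grid = simulate_events(seq)
        per_pixel = grid.occupancy()[:, 0, :].sum(axis=0)
        assert np.all(per_pixel == 1)

    def test_two_edges_draw_spacing_from_pool(self):
        gaps = set()
        for seed in range(40):
            _, offsets = make_edge_stimulus(0.5, n_edges=2, seed=seed, width=24)
            gaps.add(offsets[1] - offsets[0])
        assert gaps <= set(EDGE_SPACINGS.tolist())
        assert len(gaps) > 1

    def test_narrow_velocity_set_shape(self):
        assert len(NARROW_VELOCITIES) == 15
        assert NARROW_VELOCITIES.min() == pytest.approx(1 / 39)
        assert NARROW_VELOCITIES.max() == pytest.approx(0.04)

    def test_empty_spacing_pool_rejected(self):
        with pytest.raises(ValueError):
            make_edge_stimulus(0.5, n_edges=2, spacings=np.array([]))


class TestBarStimulus:
    def test_gray_fraction_zero_has_only_black_and_white(self):
        spec = StimulusSpec(velocity=0.5, gray_fraction=0.0, texture_length=20,
                            texture_width=3, seed=0)
        seq = make_bar_stimulus(spec, (3, 10))
        assert set(np.unique(seq.frames)) <= {0.2, 0.5, 1.0}
        rng = np.random.default_rng(0)
        tex = bar_texture(20, 0.0, rng)
        assert set(np.unique(tex)) == {0.2, 1.0}

    def test_default_texture_dimensions(self):
        spec = StimulusSpec(velocity=1.0)
        assert spec.texture_length == 80
        assert spec.texture_width == 3

    def test_texture_translates_rigidly(self):
        spec = StimulusSpec(velocity=1.0, gray_fraction=0.3, texture_length=12,
                            texture_width=1, seed=5)
        seq = make_bar_stimulus(spec, (1, 30), n_steps=20)
        # at unit velocity consecutive frames are 1-px shifts of each other
        for t in range(5, 15):
            np.testing.assert_array_equal(seq.frames[t, 0, 1:],
                                          seq.frames[t - 1, 0, :-1])

    def test_texture_wider_than_field_rejected(self):
        spec = StimulusSpec(velocity=0.5, texture_width=5)
        with pytest.raises(ValueError):
            make_bar_stimulus(spec, (3, 100))

    def test_gray_fraction_bounds(self):
        with pytest.raises(ValueError):
            StimulusSpec(velocity=0.5, gray_fraction=0.9)


class TestNoise:
    def _grid(self, T=40, H=6, W=6, dt=10.0):
        return simulate_events(
            IntensitySequence(np.full((T, H, W), 1.0), dt=dt)
        )

    def test_zero_rate_is_identity(self):
        grid = self._grid()
        out = inject_background_noise(grid, 0.0, seed=1)
        np.testing.assert_array_equal(out.counts, grid.counts)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_background_noise(self._grid(), -1.0)

    def test_original_events_preserved(self):
        frames = np.full((10, 4, 4), 1.0)
        frames[5:, 1, 1] *= np.exp(0.3)
        grid = simulate_events(IntensitySequence(frames))
        out = inject_background_noise(grid, 5.0, seed=2)
        assert np.all(out.counts >= grid.counts)

    def test_identical_seeds_identical_noise(self):
        grid = self._grid()
        a = inject_background_noise(grid, 3.0, seed=7)
        b = inject_background_noise(grid, 3.0, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_poisson_mean_within_three_standard_errors(self):
        # rate r over T bins of dt on HxW pixels adds r*dt/1000*T*H*W events
        # per polarity in expectation
        T, H, W, dt, rate = 50, 8, 8, 10.0, 4.0
        grid = self._grid(T, H, W, dt)
        totals = [
            inject_background_noise(grid, rate, seed=s).counts.sum()
            for s in range(30)
        ]
        lam_total = rate * dt * 1e-3 * T * H * W * 2
        se = np.sqrt(lam_total / len(totals))
        assert abs(np.mean(totals) - lam_total) < 3 * se
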