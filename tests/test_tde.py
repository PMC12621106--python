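"""Detector dynamics: equivalence with a straight-line oracle, update-order
semantics, and direction selectivity of the network runner."""

import numpy as np
import pytest

from tdeflow.events import StimulusSpec, make_bar_stimulus, simulate_events
from tdeflow.tde import (
    DetectorLayout,
    TDEParams,
    TDEState,
    run_tde,
    run_tde_network,
    spike_fn,
    surrogate_grad,
    tde_step,
)


def oracle_tde(fac, tr, inh, a_g, a_i, a_v, w_g, theta, variant):
    """Independent, unbatched transliteration of the detector recurrence."""
    g = i = v = 0.0
    spikes, current = [], []
    for t in range(len(fac)):
        i = a_i * i + g * tr[t]
        g = a_g * g + w_g * fac[t]
        if variant == "TDE3":
            g = g * (1.0 - inh[t])
        v = a_v * v + i
        s = 1.0 if v - theta >= 0 else 0.0
        v = (1.0 - s) * v
        spikes.append(s)
        current.append(i)
    return np.array(spikes), np.array(current)


@pytest.fixture
def params():
    return TDEParams.from_time_constants(tau_g=200, tau_i=100, tau_v=100,
                                         w_g=3.0, theta=1.0, dt=10.0)


class TestSpikeFn:
    def test_threshold_inclusive_step(self):
        assert spike_fn(-1.0) == 0
        assert spike_fn(1.0) == 1
        assert spike_fn(0.0) == 1  # fires exactly at threshold

    def test_surrogate_is_peaked_and_positive(self):
        assert surrogate_grad(0.0) > surrogate_grad(5.0) > 0
        assert surrogate_grad(0.0) == 1.0
        assert surrogate_grad(-3.0) == surrogate_grad(3.0)


class TestStepSemantics:
    @pytest.mark.parametrize("variant", ["TDE2", "TDE3"])
    def test_decay_without_input(self, params, variant):
        state = TDEState(g=2.0, i=0.5, v=0.3)
        new, s = tde_step(state, 0, 0, 0, params, variant)
        assert new.g == pytest.approx(params.alpha_g * 2.0)
        assert new.i == pytest.approx(params.alpha_i * 0.5)
        assert new.v == pytest.approx(params.alpha_v * 0.3 + new.i)
        assert s == 0

    def test_simultaneous_fac_and_inh_leaves_no_gain(self, params):
        state, _ = tde_step(TDEState(g=1.5), 1, 0, 1, params, "TDE3")
        assert state.g == 0.0

    def test_trigger_without_prior_facilitation_is_silent(self, params):
        tr = np.zeros(20)
        tr[[3, 7, 11]] = 1
        rec = run_tde(np.zeros(20), tr, np.zeros(20), params)
        assert rec.current.sum() == 0
        assert rec.spikes.sum() == 0

    @pytest.mark.parametrize("d", [1, 2, 5, 9])
    def test_delayed_trigger_injects_decayed_gain(self, params, d):
        # facilitation at t0, trigger at t0+d: injected current equals
        # w_g * alpha_g^(d-1) (the trigger reads the previous step's gain)
        t0 = 2
        fac = np.zeros(20)
        fac[t0] = 1
        tr = np.zeros(20)
        tr[t0 + d] = 1
        rec = run_tde(fac, tr, np.zeros(20), params)
        injected = rec.current[t0 + d] - params.alpha_i * rec.current[t0 + d - 1]
        assert injected == pytest.approx(params.w_g * params.alpha_g ** (d - 1))

    def test_simultaneous_fac_and_trigger_injects_nothing(self, params):
        x = np.zeros(10)
        x[4] = 1
        rec = run_tde(x, x, np.zeros(10), params)
        assert rec.current.sum() == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["TDE2", "TDE3"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_simulation(self, variant, seed):
        rng = np.random.default_rng(seed)
        T = 200
        fac, tr, inh = (rng.random(T) < 0.15 for _ in range(3))
        params = TDEParams.from_time_constants(
            tau_g=rng.uniform(20, 400), tau_i=rng.uniform(20, 400),
            tau_v=rng.uniform(20, 400), w_g=rng.uniform(0.5, 8), dt=10.0,
        )
        rec = run_tde(fac.astype(float), tr.astype(float), inh.astype(float),
                      params, variant)
        s_ref, i_ref = oracle_tde(fac, tr, inh, params.alpha_g, params.alpha_i,
                                  params.alpha_v, params.w_g, params.theta, variant)
        np.testing.assert_array_equal(rec.spikes, s_ref)
        np.testing.assert_allclose(rec.current, i_ref, rtol=0, atol=1e-12)


class TestStructuralProperties:
    def _random_case(self, seed, T=300):
        rng = np.random.default_rng(seed)
        fac, tr, inh = (rng.random(T) < 0.2 for _ in range(3))
        params = TDEParams.from_time_constants(
            tau_g=rng.uniform(20, 400), tau_i=rng.uniform(20, 400),
            tau_v=rng.uniform(20, 400), w_g=rng.uniform(0.5, 8), dt=10.0,
        )
        return fac.astype(float), tr.astype(float), inh.astype(float), params

    @pytest.mark.parametrize("seed", range(4))
    def test_tde2_equals_tde3_without_inhibitor_events(self, seed):
        fac, tr, _, params = self._random_case(seed)
        r2 = run_tde(fac, tr, np.zeros_like(fac), params, "TDE2")
        r3 = run_tde(fac, tr, np.zeros_like(fac), params, "TDE3")
        np.testing.assert_array_equal(r2.spikes, r3.spikes)
        np.testing.assert_array_equal(r2.current, r3.current)

    @pytest.mark.parametrize("seed", range(4))
    def test_voltage_resets_after_each_spike(self, seed):
        fac, tr, inh, params = self._random_case(seed)
        state = TDEState(g=0.0, i=0.0, v=0.0)
        for t in range(len(fac)):
            state, s = tde_step(state, fac[t], tr[t], inh[t], params, "TDE3")
            if s:
                assert state.v == 0.0
            assert state.g >= 0.0  # gain never negative for binary inputs


class TestNetwork:
    def test_static_scene_is_silent(self, params):
        from tdeflow.events import EventGrid

        grid = EventGrid(np.zeros((20, 2, 6, 12), dtype=int), dt=10.0)
        layout = DetectorLayout(height=6, width=12, variant="TDE3")
        recs = run_tde_network(grid, layout, params)
        assert all(rec.spikes.sum() == 0 for rec in recs.values())

    def test_tde3_spikes_only_in_preferred_channel(self, params):
        spec = StimulusSpec(velocity=0.5, direction="L-R", gray_fraction=0.0,
                            texture_length=20, texture_width=6, seed=3)
        seq = make_bar_stimulus(spec, (6, 16), dt=10.0)
        grid = simulate_events(seq)
        layout = DetectorLayout(height=6, width=16, variant="TDE3",
                                channels=("L-R", "R-L"))
        recs = run_tde_network(grid, layout, params)
        assert recs["L-R"].spikes.sum() > 0
        assert recs["R-L"].spikes.sum() == 0

    def test_tde2_fires_on_second_null_direction_edge(self, params):
        # two R-L edges crossing a L-R detector: the first leaves residual
        # gain that the second triggers
        T, W = 40, 12
        occ = np.zeros((T, 1, W))
        for off, t0 in ((0, 2), (4, 10)):  # two edges sweeping right-to-left
            for k in range(W):
                t = t0 + k
                if t < T:
                    occ[t, 0, W - 1 - k] = 1
        from tdeflow.events import EventGrid

        counts = np.zeros((T, 2, 1, W), dtype=int)
        counts[:, 0] = occ
        grid = EventGrid(counts, dt=10.0)
        lay2 = DetectorLayout(height=1, width=W, variant="TDE2", channels=("L-R",))
        lay3 = DetectorLayout(height=1, width=W, variant="TDE3", channels=("L-R",))
        s2 = run_tde_network(grid, lay2, params)["L-R"].spikes.sum()
        s3 = run_tde_network(grid, lay3, params)["L-R"].spikes.sum()
        assert s2 > 0  # TDE-2 loses direction selectivity on textures
        assert s3 == 0  # the inhibitor wipes the residual gain

    def test_layout_rejects_oversized_spacing(self, params):
        from tdeflow.events import EventGrid

        grid = EventGrid(np.zeros((5, 2, 4, 8), dtype=int), dt=10.0)
        layout = DetectorLayout(height=4, width=8, spacing=4, variant="TDE3")
        with pytest.raises(ValueError):
            run_tde_network(grid, layout, params)
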