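"""Training loop: loss arithmetic, gradient correctness (analytic BPTT vs
the tape reference, surrogate vs finite differences across a spike flip),
convergence, determinism, and regularization pressure."""

import numpy as np
import pytest

from tdeflow.autograd import Var, as_var
from tdeflow.training import (
    EdgeTaskGenerator,
    TrainConfig,
    _batch_loss,
    _estimates_on_tape,
    _forward_tape,
    _recurrence_backward,
    _run_recurrence,
    default_inference_config,
    init_high_activity,
    train_tde,
    velocity_loss,
)


@pytest.fixture(scope="module")
def wide_gen():
    return EdgeTaskGenerator("wide", 1)


class TestVelocityLoss:
    def test_perfect_estimate_zero_spikes_is_zero(self):
        est = [as_var(0.4), as_var(0.8), as_var(0.2)]
        loss = velocity_loss(est, [0.4, 0.8, 0.2], [0.0, 0.0, 0.0],
                             TrainConfig())
        assert loss.data == pytest.approx(0.0, abs=1e-4)

    def test_rescaled_mapping_is_penalized(self):
        # the joint normalizer pins absolute scale: a proportionally shrunk
        # estimate vector is NOT loss-free (else the sparsity term could
        # shrink the mapping without bound)
        cfg = TrainConfig()
        exact = velocity_loss([as_var(0.5), as_var(1.0)], [0.5, 1.0], [0.0, 0.0], cfg)
        shrunk = velocity_loss([as_var(0.25), as_var(0.5)], [0.5, 1.0], [0.0, 0.0], cfg)
        assert exact.data == pytest.approx(0.0, abs=1e-4)
        assert shrunk.data > 0.1

    def test_zero_estimates_cost_mean_normalized_truth(self):
        cfg = TrainConfig()
        loss = velocity_loss([as_var(0.0), as_var(0.0)], [0.5, 1.0],
                             [0.0, 0.0], cfg)
        assert loss.data == pytest.approx((0.5 + 1.0) / 2, abs=1e-4)

    def test_regularization_arithmetic(self):
        # one example with 10 spikes: 0.05 * (1e-2 * 100)^0.5 = 0.05
        cfg = TrainConfig()
        loss = velocity_loss([], [], [10.0], cfg)
        assert loss.data == pytest.approx(0.05, abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("mode,noise", [("count", 0.0), ("isi", 0.0),
                                            ("count", 2.0)])
    def test_analytic_bptt_matches_tape_reference(self, mode, noise):
        gen = EdgeTaskGenerator("wide", 1 if noise == 0 else 2, noise_rate=noise)
        cfg = TrainConfig(mode=mode, velocity_set="wide", noise_rate=noise,
                          batch_size=5, seed=0)
        batch = gen.sample_batch(np.random.default_rng(3), 5)
        values = init_high_activity()
        values["w_g"] = 2.5
        if noise > 0:
            values["n"] = 1.3
        icfg = default_inference_config(mode, "wide")

        def loss_and_leafgrads():
            fwd = _run_recurrence(batch, values, cfg)
            T = fwd["S"].shape[0]
            s_l = [Var(fwd["S"][t]) for t in range(T)]
            i_l = [Var(fwd["I"][t]) for t in range(T)]
            parts = _estimates_on_tape(batch, s_l, i_l, cfg, icfg)
            ss = as_var(np.zeros(5))
            for s in s_l:
                ss = ss + s
            loss = _batch_loss(*parts, ss, cfg)
            loss.backward()
            z = np.zeros(5)
            dS = np.stack([l.grad if l.grad is not None else z for l in s_l])
            dI = np.stack([l.grad if l.grad is not None else z for l in i_l])
            return loss, _recurrence_backward(fwd, dS, dI, batch, cfg)

        loss_a, g_analytic = loss_and_leafgrads()

        pv = {k: Var(v) for k, v in values.items()}
        s_l, i_l = _forward_tape(batch, pv, cfg)
        parts = _estimates_on_tape(batch, s_l, i_l, cfg, icfg)
        ss = as_var(np.zeros(5))
        for s in s_l:
            ss = ss + s
        loss_t = _batch_loss(*parts, ss, cfg)
        loss_t.backward()
        assert loss_a.data == pytest.approx(loss_t.data, rel=1e-12)
        for k in values:
            tape_g = float(np.sum(pv[k].grad)) if pv[k].grad is not None else 0.0
            assert g_analytic.get(k, 0.0) == pytest.approx(tape_g, rel=1e-9, abs=1e-15)

    def test_surrogate_gradient_sign_matches_loss_jump(self):
        # the decoded loss is piecewise constant in w_g (spikes are binary),
        # so compare the surrogate gradient's sign with the sign of the loss
        # change across a w_g step large enough to flip a spike
        gen = EdgeTaskGenerator("wide", 1)
        cfg = TrainConfig(mode="count", velocity_set="wide", batch_size=4, seed=0)
        batch = gen.sample_batch(np.random.default_rng(5), 4)
        icfg = default_inference_config("count", "wide")

        def loss_of(wg, want_grad=False):
            values = init_high_activity()
            values["w_g"] = wg
            fwd = _run_recurrence(batch, values, cfg)
            T = fwd["S"].shape[0]
            s_l = [Var(fwd["S"][t]) for t in range(T)]
            i_l = [Var(fwd["I"][t]) for t in range(T)]
            parts = _estimates_on_tape(batch, s_l, i_l, cfg, icfg)
            ss = as_var(np.zeros(4))
            for s in s_l:
                ss = ss + s
            loss = _batch_loss(*parts, ss, cfg)
            if not want_grad:
                return float(loss.data)
            loss.backward()
            z = np.zeros(4)
            dS = np.stack([l.grad if l.grad is not None else z for l in s_l])
            dI = np.stack([l.grad if l.grad is not None else z for l in i_l])
            return float(loss.data), _recurrence_backward(fwd, dS, dI, batch, cfg)

        _, grads = loss_of(5.0, want_grad=True)
        jump = loss_of(5.0 + 1.0) - loss_of(5.0 - 1.0)
        assert grads["w_g"] != 0.0
        assert np.sign(grads["w_g"]) == np.sign(jump)


class TestTrainingLoop:
    def test_loss_decreases_on_wide_count_task(self, wide_gen):
        cfg = TrainConfig(mode="count", velocity_set="wide", epochs=120,
                          batch_size=60, seed=2)
        _, _, hist = train_tde(wide_gen, cfg)
        assert np.mean(hist.loss[-10:]) < np.mean(hist.loss[:10])

    def test_identical_seeds_give_identical_histories(self, wide_gen):
        cfg = TrainConfig(mode="count", velocity_set="wide", epochs=15,
                          batch_size=30, seed=7)
        _, _, h1 = train_tde(wide_gen, cfg)
        _, _, h2 = train_tde(wide_gen, cfg)
        assert h1.loss == h2.loss
        assert h1.mean_spikes == h2.mean_spikes

    def test_stronger_regularization_never_increases_spiking(self, wide_gen):
        converged = []
        for rw in (0.01, 0.05, 0.25):
            cfg = TrainConfig(mode="count", velocity_set="wide", epochs=800,
                              batch_size=60, seed=3, reg_weight=rw)
            _, _, hist = train_tde(wide_gen, cfg)
            converged.append(np.mean(hist.mean_spikes[-50:]))
        # monotone within a stochastic tolerance of 10%
        assert converged[1] <= converged[0] * 1.1
        assert converged[2] <= converged[1] * 1.1

    def test_history_lengths_match_epochs(self, wide_gen):
        cfg = TrainConfig(mode="isi", velocity_set="wide", epochs=8,
                          batch_size=20, seed=0)
        _, _, hist = train_tde(wide_gen, cfg)
        assert len(hist.loss) == len(hist.mean_spikes) == len(hist.correlation) == 8


class TestGenerator:
    def test_trigger_delay_is_reciprocal_velocity(self):
        gen = EdgeTaskGenerator("wide", 1)
        batch = gen.sample_batch(np.random.default_rng(0), 50)
        fac, tr = batch["fac"], batch["tr"]
        for b in range(50):
            tf = np.flatnonzero(fac[b])[0]
            tt = np.flatnonzero(tr[b])[0]
            d = round(1.0 / batch["v_true"][b])
            assert tt - tf == d

    def test_two_edge_batches_have_two_trigger_events(self):
        gen = EdgeTaskGenerator("wide", 2)
        batch = gen.sample_batch(np.random.default_rng(1), 20)
        for b in range(20):
            assert len(batch["edge_times"][b]) == 2

    def test_noisy_batches_are_seed_deterministic(self):
        gen = EdgeTaskGenerator("wide", 2, noise_rate=1.0)
        b1 = gen.sample_batch(np.random.default_rng(5), 4)
        b2 = gen.sample_batch(np.random.default_rng(5), 4)
        np.testing.assert_array_equal(b1["vnb_tr"], b2["vnb_tr"])
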