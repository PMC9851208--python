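"""Update rules, AdaGrad, and the training loop."""

import dataclasses

import numpy as np
import pytest

from eqadapt.data import make_blobs
from eqadapt.errors import ConfigurationError, ValidationError
from eqadapt.learning import (
    AdaGradState,
    TrainConfig,
    UpdateSet,
    adagrad_apply,
    apply_updates,
    chl_update,
    classification_error,
    ep_update,
    predictive_update,
    train,
)
from eqadapt.network import ActivityState, LayeredNetwork, PhaseResult, PhaseSchedule, run_phases


def make_result(net, hat_layers, free_layers, schedule):
    hat = ActivityState(hat_layers)
    free = ActivityState(free_layers)
    return PhaseResult(free_state=free, clamped_state=hat, adapted_state=hat, schedule=schedule)


@pytest.fixture
def scalar_net():
    """1-1-1 chain so rule arithmetic can be checked by hand."""
    return LayeredNetwork([1, 1, 1], [np.ones((1, 1)), np.ones((1, 1))], [np.zeros(1), np.zeros(1)])


class TestRuleArithmetic:
    def test_ep_update_hand_example(self, scalar_net):
        # dw = (alpha/beta) * (0.6*0.8 - 0.5*0.6) = (0.1/0.5) * 0.18 = 0.036
        sched = PhaseSchedule(clamp_mode="soft", beta=0.5)
        result = make_result(
            scalar_net,
            [[[1.0]], [[0.6]], [[0.8]]],
            [[[1.0]], [[0.5]], [[0.6]]],
            sched,
        )
        cfg = TrainConfig(rule="ep", learning_rates=0.1, optimizer="none")
        upd = ep_update(result, scalar_net, cfg)
        assert np.isclose(upd.weights[1][0, 0], 0.036)

    def test_chl_update_hand_example(self, scalar_net):
        # same activities without 1/beta: 0.1 * 0.18 = 0.018
        sched = PhaseSchedule(clamp_mode="hard")
        result = make_result(
            scalar_net, [[[1.0]], [[0.6]], [[0.8]]], [[[1.0]], [[0.5]], [[0.6]]], sched
        )
        cfg = TrainConfig(rule="chl", learning_rates=0.1, optimizer="none")
        upd = chl_update(result, scalar_net, cfg)
        assert np.isclose(upd.weights[1][0, 0], 0.018)

    def test_predictive_update_hand_example(self, scalar_net):
        # dw = alpha * x^_pre * (x^_post - xv_post) = 0.1 * 0.5 * 0.2 = 0.01
        sched = PhaseSchedule(clamp_mode="soft", beta=1.0)
        result = make_result(
            scalar_net, [[[1.0]], [[0.5]], [[0.8]]], [[[1.0]], [[0.4]], [[0.6]]], sched
        )
        cfg = TrainConfig(rule="predictive_ep", learning_rates=0.1, optimizer="none")
        upd = predictive_update(result, scalar_net, cfg)
        assert np.isclose(upd.weights[1][0, 0], 0.01)

    def test_identical_phases_give_zero_updates(self, small_net):
        sched = PhaseSchedule(clamp_mode="soft", beta=0.5)
        layers = [np.full((1, 3), 0.4), np.full((1, 4), 0.7), np.full((1, 2), 0.2)]
        result = make_result(small_net, layers, [a.copy() for a in layers], sched)
        for rule, fn in (("ep", ep_update), ("chl", chl_update)):
            upd = fn(result, small_net, TrainConfig(rule=rule, optimizer="none"))
            assert all(np.all(w == 0) for w in upd.weights)
            assert all(np.all(b == 0) for b in upd.biases)

    def test_predictive_zero_when_post_gaps_vanish(self, small_net):
        sched = PhaseSchedule(clamp_mode="hard")
        free = [np.full((1, 3), 0.4), np.full((1, 4), 0.7), np.full((1, 2), 0.2)]
        hat = [np.full((1, 3), 0.9), free[1].copy(), free[2].copy()]  # only pre differs
        result = make_result(small_net, hat, free, sched)
        upd = predictive_update(result, small_net, TrainConfig(rule="predictive_chl", optimizer="none"))
        assert all(np.all(w == 0) for w in upd.weights)

    def test_ep_equals_chl_divided_by_beta(self, small_net):
        rng = np.random.default_rng(5)
        sched = PhaseSchedule(clamp_mode="soft", beta=0.37)
        hat = [rng.uniform(0, 1, (4, s)) for s in (3, 4, 2)]
        free = [hat[0], rng.uniform(0, 1, (4, 4)), rng.uniform(0, 1, (4, 2))]
        result = make_result(small_net, hat, free, sched)
        cfg_e = TrainConfig(rule="ep", learning_rates=0.2, optimizer="none")
        cfg_c = TrainConfig(rule="chl", learning_rates=0.2, optimizer="none")
        e = ep_update(result, small_net, cfg_e)
        c = chl_update(result, small_net, cfg_c)
        for we, wc in zip(e.weights, c.weights):
            assert np.allclose(we, wc / sched.beta)

    def test_predictive_minus_ep_identity(self, small_net):
        # per entry: predictive - ep = (1/beta) * alpha * xv_post * (xv_pre - x^_pre)
        # (expand x^_pre(x^_post - xv_post) - (x^_pre x^_post - xv_pre xv_post))
        rng = np.random.default_rng(6)
        sched = PhaseSchedule(clamp_mode="soft", beta=0.5)
        hat = [rng.uniform(0, 1, (3, s)) for s in (3, 4, 2)]
        free = [rng.uniform(0, 1, (3, s)) for s in (3, 4, 2)]
        result = make_result(small_net, hat, free, sched)
        alpha = 0.1
        cfg_p = TrainConfig(rule="predictive_ep", learning_rates=alpha, optimizer="none")
        cfg_e = TrainConfig(rule="ep", learning_rates=alpha, optimizer="none")
        p = predictive_update(result, small_net, cfg_p)
        e = ep_update(result, small_net, cfg_e)
        B = 3
        for i in range(2):
            expected = (alpha / sched.beta) * (
                (ActivityState(free).layers[i] - ActivityState(hat).layers[i]).T
                @ ActivityState(free).layers[i + 1]
            ) / B
            assert np.allclose(p.weights[i] - e.weights[i], expected)

    def test_full_adaptation_kills_predictive_update(self, small_net):
        # c = 1 snaps the adapted state onto the free steady state
        sched = PhaseSchedule(n_free=60, n_clamped=60, teach_delay=0, n_adapt=1, c=1.0)
        result = run_phases(small_net, np.array([0.2, 0.4, 0.8]), np.array([1.0, 0.0]), sched)
        upd = predictive_update(
            result, small_net, TrainConfig(rule="predictive_chl", optimizer="none")
        )
        assert all(np.all(w == 0) for w in upd.weights)
        assert all(np.all(b == 0) for b in upd.biases)

    def test_ep_requires_positive_beta(self, scalar_net):
        sched = PhaseSchedule(clamp_mode="hard", beta=0.0)
        result = make_result(
            scalar_net, [[[1.0]], [[0.6]], [[0.8]]], [[[1.0]], [[0.5]], [[0.6]]], sched
        )
        with pytest.raises(ConfigurationError):
            ep_update(result, scalar_net, TrainConfig(rule="ep", optimizer="none"))

    def test_lateral_updates_have_zero_diagonal(self):
        net = LayeredNetwork.initialize([3, 4, 2], seed=2, lateral_layers=[1])
        rng = np.random.default_rng(3)
        sched = PhaseSchedule(clamp_mode="hard")
        hat = [rng.uniform(0, 1, (2, s)) for s in (3, 4, 2)]
        free = [rng.uniform(0, 1, (2, s)) for s in (3, 4, 2)]
        result = make_result(net, hat, free, sched)
        upd = chl_update(result, net, TrainConfig(rule="chl", optimizer="none"))
        assert np.all(np.diagonal(upd.laterals[1]) == 0)
        assert np.any(upd.laterals[1] != 0)


class TestAdaGrad:
    def _single(self, g, alpha=1.0):
        net = LayeredNetwork([1, 1], [np.zeros((1, 1))], [np.zeros(1)])
        upd = UpdateSet([np.array([[g]])], [np.zeros(1)], {}, alpha=[alpha])
        return net, upd

    def test_first_step_is_sign_preserving_unit_scale(self):
        net, upd = self._single(0.3)
        cfg = TrainConfig(optimizer="adagrad", adagrad_epsilon=1e-12)
        eff, acc = adagrad_apply(upd, AdaGradState.zeros_like(net), cfg)
        assert np.isclose(eff.weights[0][0, 0], 1.0, atol=1e-6)
        assert np.isclose(acc.weights[0][0, 0], 0.09)

    def test_zero_update_changes_nothing(self):
        net, upd = self._single(0.0)
        cfg = TrainConfig(optimizer="adagrad")
        acc0 = AdaGradState.zeros_like(net)
        eff, acc = adagrad_apply(upd, acc0, cfg)
        assert np.all(eff.weights[0] == 0)
        assert np.all(acc.weights[0] == 0)

    def test_second_equal_step_shrinks_by_sqrt_two(self):
        net, upd = self._single(-0.5)
        cfg = TrainConfig(optimizer="adagrad", adagrad_epsilon=1e-12)
        acc = AdaGradState.zeros_like(net)
        _, acc = adagrad_apply(upd, acc, cfg)
        eff2, _ = adagrad_apply(upd, acc, cfg)
        assert np.isclose(eff2.weights[0][0, 0], -1.0 / np.sqrt(2.0), atol=1e-6)

    def test_learning_rate_scales_effective_step(self):
        # with delta = alpha * g the effective step is alpha * g / |g|
        net, upd = self._single(0.3 * 0.1, alpha=0.1)
        cfg = TrainConfig(optimizer="adagrad", adagrad_epsilon=1e-12)
        eff, _ = adagrad_apply(upd, AdaGradState.zeros_like(net), cfg)
        assert np.isclose(eff.weights[0][0, 0], 0.1, atol=1e-6)


class TestTraining:
    def _dataset(self, seed=0):
        return make_blobs(n=120, d=4, k=2, separation=4.0, noise_sd=0.15, seed=seed)

    def _config(self, **kw):
        base = dict(
            rule="predictive_chl",
            learning_rates=0.5,
            optimizer="adagrad",
            batch_size=20,
            n_epochs=3,
            seed=1,
        )
        base.update(kw)
        return TrainConfig(**base)

    def test_metrics_log_deterministic_given_seed(self, short_schedule):
        ds = self._dataset()
        runs = []
        for _ in range(2):
            net = LayeredNetwork.initialize([4, 6, 2], seed=4, feedback_gain=0.5)
            _, m = train(net, ds, short_schedule, self._config())
            runs.append(m.drop(columns=["wall_time_s"]))
        assert runs[0].equals(runs[1])

    def test_no_adaptation_paths_bitwise_identical(self, short_schedule):
        # c = 0 with many adaptation steps must equal n_adapt = 0 exactly
        ds = self._dataset()
        s_c0 = dataclasses.replace(short_schedule, c=0.0, n_adapt=20)
        s_na = dataclasses.replace(short_schedule, n_adapt=0)
        outs = []
        for sched in (s_c0, s_na):
            net = LayeredNetwork.initialize([4, 6, 2], seed=4, feedback_gain=0.5)
            net, m = train(net, ds, sched, self._config())
            outs.append((net, m.drop(columns=["wall_time_s"])))
        assert outs[0][1].equals(outs[1][1])
        for a, b in zip(outs[0][0].weights, outs[1][0].weights):
            assert np.array_equal(a, b)

    def test_learns_separable_blobs(self, short_schedule):
        ds = make_blobs(n=300, d=8, k=2, separation=3.0, noise_sd=0.05, seed=0)
        net = LayeredNetwork.initialize([8, 12, 2], seed=0, feedback_gain=0.5)
        cfg = self._config(n_epochs=8)
        net, m = train(net, ds, short_schedule, cfg)
        assert m["train_error"].iloc[-1] < 0.05

    def test_targets_matching_free_output_give_zero_updates(self):
        # predictive rule: clamping to the free-phase output changes nothing
        # (free phase run to numerical convergence so the nudge term vanishes)
        net = LayeredNetwork.initialize([4, 6, 2], seed=9, feedback_gain=0.5)
        from eqadapt.network import run_free_phase

        sched = PhaseSchedule(
            n_free=400, n_clamped=100, teach_delay=0, n_adapt=0, h=0.5,
            clamp_mode="soft", beta=0.3,
        )
        X = np.random.default_rng(0).uniform(0, 1, (5, 4))
        free, _ = run_free_phase(net, X, sched, record_trace=False)
        Y = free.layers[-1]
        result = run_phases(net, X, Y, sched)
        upd = predictive_update(
            result, net, TrainConfig(rule="predictive_ep", optimizer="none")
        )
        for w in upd.weights:
            assert np.max(np.abs(w)) < 1e-9

    def test_adaptation_attenuates_predictive_update_magnitude(self):
        # only the output layer differs between phases on this toy chain, so
        # the update after n adaptation steps scales as (1 - c)^n
        net = LayeredNetwork([1, 1], [np.ones((1, 1))], [np.zeros(1)])
        free = ActivityState([[[0.5]], [[0.2]]])
        hat = ActivityState([[[0.5]], [[0.9]]])
        cfg = TrainConfig(rule="predictive_chl", learning_rates=1.0, optimizer="none")
        mags = []
        for n_adapt in (0, 5):
            sched = PhaseSchedule(clamp_mode="hard", n_adapt=n_adapt, c=0.2)
            from eqadapt.network import run_adaptation

            adapted, _ = run_adaptation(hat, free, sched)
            result = PhaseResult(free, hat, adapted, sched)
            upd = predictive_update(result, net, cfg)
            mags.append(abs(upd.weights[0][0, 0]))
        # the presynaptic input is identical across phases, so attenuation is
        # exactly the post-gap factor (1 - c)^n
        assert np.isclose(mags[1] / mags[0], 0.8**5, rtol=1e-10)

    def test_empty_dataset_rejected(self, short_schedule):
        ds = self._dataset()
        ds.split[:] = "test"
        net = LayeredNetwork.initialize([4, 6, 2], seed=4)
        with pytest.raises(ValidationError):
            train(net, ds, short_schedule, self._config())

    def test_classification_error_range(self, short_schedule):
        ds = self._dataset()
        net = LayeredNetwork.initialize([4, 6, 2], seed=4)
        Xtr, Ytr, _, _ = ds.train_test()
        err = classification_error(net, Xtr, Ytr, short_schedule)
        assert 0.0 <= err <= 1.0
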