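"""Trace-based STDP, population-coded reward, and co-learning schedules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stp.blocks import BlockConfig
from stp.errors import ContractError
from stp.network import HeadSpec, NetworkPlan, build_network
from stp.plasticity import (GlobalPhase, LocalPhase, PlasticityState,
                            RewardSpec, apply_update, co_learning_schedule,
                            compute_reward, hebb_delta, register_rule,
                            stdp_delta, update_traces)
from stp.synthetic import gen_synthetic_motion
from stp.training import TrainConfig, bptt_train


def fresh_state(n_in=1, n_out=1, theta=0.95, eta=1.0):
    return PlasticityState.zeros(n_in, n_out, theta=theta, eta=eta)


class TestTraces:
    def test_degenerate_trace_equals_current_spike(self):
        ps = fresh_state(theta=0.0, eta=1.0)
        ps = update_traces(ps, [1.0], [0.0])
        assert ps.t_in[0] == 1.0 and ps.t_out[0] == 0.0
        ps = update_traces(ps, [0.0], [1.0])
        assert ps.t_in[0] == 0.0 and ps.t_out[0] == 1.0

    def test_two_step_decay(self):
        ps = fresh_state()
        ps = update_traces(ps, [1.0], [0.0])
        ps = update_traces(ps, [0.0], [0.0])
        assert ps.t_in[0] == pytest.approx(0.95)

    def test_silence_decays_geometrically(self):
        ps = fresh_state()
        ps = update_traces(ps, [1.0], [1.0])
        for k in range(1, 6):
            ps = update_traces(ps, [0.0], [0.0])
            assert ps.t_in[0] == pytest.approx(0.95**k)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            update_traces(fresh_state(2, 3), [1.0], [0.0, 0.0, 0.0])


class TestSTDP:
    def simulate_pair(self, first, second, gap=1):
        """Two single spikes separated by `gap` silent steps; returns dW at
        the second spike."""
        ps = fresh_state()
        spikes = {"in": [0.0], "out": [0.0]}
        seq = [(first, 1.0)] + [(None, 0.0)] * (gap - 1) + [(second, 1.0)]
        for site, val in seq:
            s_in = [val] if site == "in" else [0.0]
            s_out = [val] if site == "out" else [0.0]
            ps = update_traces(ps, s_in, s_out)
            dw = stdp_delta(ps, s_in, s_out)
        return dw[0, 0]

    def test_pre_before_post_potentiates(self):
        assert self.simulate_pair("in", "out") == pytest.approx(0.95)

    def test_post_before_pre_depresses(self):
        assert self.simulate_pair("out", "in") == pytest.approx(-0.95)

    def test_simultaneous_spikes_cancel(self):
        ps = fresh_state()
        ps = update_traces(ps, [1.0], [1.0])
        assert stdp_delta(ps, [1.0], [1.0])[0, 0] == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(1, 6), st.floats(0.1, 0.99))
    def test_antisymmetry_of_pair_updates(self, gap, theta):
        """Swapping the spike order exactly negates dW: with unit traces the
        magnitude is theta**gap either way."""
        def pair(first, second):
            p = PlasticityState.zeros(1, 1, theta=theta, eta=1.0)
            seq = [(first, 1.0)] + [(None, 0.0)] * (gap - 1) + [(second, 1.0)]
            for site, val in seq:
                s_in = [val] if site == "in" else [0.0]
                s_out = [val] if site == "out" else [0.0]
                p = update_traces(p, s_in, s_out)
                dw = stdp_delta(p, s_in, s_out)
            return dw[0, 0]

        assert pair("in", "out") == pytest.approx(-pair("out", "in"))
        assert pair("in", "out") == pytest.approx(theta**gap)

    def test_hebb_rule_is_plain_coincidence(self):
        """With theta=0, eta=1 the trace STDP vanishes for coincident
        spikes; the Hebb rule uses the raw outer product instead."""
        ps = fresh_state(theta=0.0, eta=1.0)
        ps = update_traces(ps, [1.0], [1.0])
        assert stdp_delta(ps, [1.0], [1.0])[0, 0] == 0.0
        assert hebb_delta(ps, [1.0], [1.0])[0, 0] == 1.0


class TestReward:
    def spec(self, label_cat=0, n=7, cats=3):
        onehot = np.zeros(cats)
        onehot[label_cat] = 1.0
        return RewardSpec(n_per_category=n, n_categories=cats, label=onehot)

    def test_zero_exactly_at_label_pattern(self):
        spec = self.spec(label_cat=1)
        out = np.concatenate([np.zeros(7), np.ones(7), np.zeros(7)])
        assert not compute_reward(out, spec).any()

    def test_silent_output_rewards_label_category_only(self):
        r = compute_reward(np.zeros(21), self.spec(label_cat=2))
        np.testing.assert_array_equal(r[:14], 0.0)
        np.testing.assert_array_equal(r[14:], 1.0)

    def test_partial_population_hand_case(self):
        # category 0 fires 4 of its 7 neurons: O = 4/7, r = 3/7
        out = np.concatenate([[1, 1, 1, 1, 0, 0, 0], np.zeros(14)])
        r = compute_reward(out, self.spec(label_cat=0))
        np.testing.assert_allclose(r[:7], 3 / 7)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ContractError):
            compute_reward(np.zeros(20), self.spec())


class TestApplyUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        w = rng.normal(size=(4, 6))
        ps = PlasticityState.zeros(4, 6, lr=0.0)
        np.testing.assert_array_equal(
            apply_update(w, np.ones((4, 6)), np.ones(6), ps), w)

    def test_zero_reward_is_identity(self, rng):
        w = rng.normal(size=(4, 6))
        ps = PlasticityState.zeros(4, 6, lr=0.5)
        np.testing.assert_array_equal(
            apply_update(w, np.ones((4, 6)), np.zeros(6), ps), w)

    def test_unit_case_moves_by_lr(self):
        ps = PlasticityState.zeros(1, 1, lr=0.001)
        w = apply_update(np.zeros((1, 1)), np.ones((1, 1)), np.ones(1), ps)
        assert w[0, 0] == pytest.approx(0.001)

    def test_shape_mismatch_rejected(self):
        ps = PlasticityState.zeros(2, 2)
        with pytest.raises(ContractError):
            apply_update(np.zeros((2, 2)), np.zeros((2, 3)), None, ps)


class TestCoLearning:
    def pop_plan(self):
        return NetworkPlan(
            blocks=[BlockConfig(kind="fc_lif", in_channels=128,
                                out_channels=6)],
            input_shape=(2, 8, 8), t_total=8,
            head=HeadSpec(kind="population", n_classes=2, n_per_category=3),
            aggregation="mean",
        )

    def data(self):
        return gen_synthetic_motion(classes=("left", "right"), t_steps=8,
                                    hw=(8, 8), n_samples=12, seed=0)

    def test_global_only_schedule_equals_plain_bptt(self):
        cfg = TrainConfig(epochs=2, batch_size=6, seed=0)
        a = build_network(self.pop_plan(), seed=1)
        co_learning_schedule(a, [GlobalPhase(train=cfg)], self.data())
        b = build_network(self.pop_plan(), seed=1)
        bptt_train(b, self.data(), cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_local_phase_with_zero_lr_changes_nothing(self):
        net = build_network(self.pop_plan(), seed=1)
        before = [p.data.copy() for p in net.parameters()]
        co_learning_schedule(net, [LocalPhase(lr=0.0)], self.data())
        for p, b in zip(net.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_local_phase_touches_only_target_layer(self):
        from stp.neurons import NeuronParams

        # low thresholds guarantee spiking activity for the local updates
        plan = NetworkPlan(
            blocks=[
                BlockConfig(kind="fc_lif", in_channels=128, out_channels=16,
                            neuron=NeuronParams(alpha=0.7, v_th=0.1)),
                BlockConfig(kind="fc_lif", in_channels=16, out_channels=6,
                            neuron=NeuronParams(alpha=0.7, v_th=0.1)),
            ],
            input_shape=(2, 8, 8), t_total=8,
            head=HeadSpec(kind="population", n_classes=2, n_per_category=3),
            aggregation="mean",
        )
        net = build_network(plan, seed=1)
        w_hidden = net.blocks[0].w.data.copy()
        w_out = net.blocks[1].w.data.copy()
        co_learning_schedule(net, [LocalPhase(lr=0.05)], self.data())
        np.testing.assert_array_equal(net.blocks[0].w.data, w_hidden)
        assert not np.array_equal(net.blocks[1].w.data, w_out)

    def test_custom_rule_registry(self):
        register_rule("null", lambda ps, s_in, s_out, r, w: np.zeros(
            (len(s_in), len(s_out))))
        net = build_network(self.pop_plan(), seed=1)
        before = net.blocks[0].w.data.copy()
        co_learning_schedule(net, [LocalPhase(rule="null", lr=1.0)],
                             self.data())
        np.testing.assert_array_equal(net.blocks[0].w.data, before)

    def test_unknown_rule_rejected(self):
        net = build_network(self.pop_plan(), seed=1)
        with pytest.raises(ContractError):
            co_learning_schedule(net, [LocalPhase(rule="ghost")], self.data())
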