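"""Iteration modes: IIM/EIM equivalence, streaming, and reset semantics."""

import numpy as np
import pytest

from stp import Tensor
from stp.blocks import BlockConfig
from stp.errors import ContractError, PlanError, StaleStateError
from stp.network import HeadSpec, NetworkPlan, build_network, reset_states
from stp.neurons import NeuronParams


def plan_variants():
    lif = NetworkPlan(
        blocks=[
            BlockConfig(kind="conv_lif", in_channels=2, out_channels=4,
                        stride=(2, 2)),
            BlockConfig(kind="fc_lif", in_channels=4 * 3 * 3, out_channels=6),
        ],
        input_shape=(2, 6, 6), t_total=5,
        head=HeadSpec(kind="linear", n_classes=3), aggregation="sum",
    )
    liaf_bn = NetworkPlan(
        blocks=[
            BlockConfig(kind="conv_liaf", in_channels=1, out_channels=3,
                        norm="batchnorm"),
            BlockConfig(kind="conv2d_td", in_channels=3, out_channels=2),
        ],
        input_shape=(1, 5, 5), t_total=4,
        head=HeadSpec(kind="linear", n_classes=2), aggregation="mean",
    )
    soft_csm = NetworkPlan(
        blocks=[
            BlockConfig(
                kind="conv_lif", in_channels=2, out_channels=3,
                neuron=NeuronParams(
                    alpha=np.array([0.5, 0.7, 0.9]), beta=np.zeros(3),
                    v_th=np.array([0.8, 1.0, 1.2]), v_reset=np.zeros(3),
                    reset_mode="soft", sharing_mode="csm"),
            ),
        ],
        input_shape=(2, 4, 4), t_total=6,
        head=None, aggregation="last_step",
    )
    population = NetworkPlan(
        blocks=[
            BlockConfig(kind="fc_lif", in_channels=8, out_channels=6),
        ],
        input_shape=(8,), t_total=7,
        head=HeadSpec(kind="population", n_classes=3, n_per_category=2),
        aggregation="mean",
    )
    return {"lif": lif, "liaf_bn": liaf_bn, "soft_csm": soft_csm,
            "population": population}


@pytest.fixture(params=list(plan_variants()))
def built_net(request):
    plan = plan_variants()[request.param]
    return build_network(plan, seed=3), plan


def random_input(plan, rng, batch=3):
    return rng.normal(0.7, 0.8, (batch, plan.t_total) + tuple(plan.input_shape))


class TestModeEquivalence:
    def test_iim_equals_eim_bitwise(self, built_net, rng):
        net, plan = built_net
        x = random_input(plan, rng)
        a = net.run_iim(Tensor(x))
        b = net.run_eim(Tensor(x))
        assert np.array_equal(a.data, b.data)

    def test_streaming_equals_batched(self, built_net, rng):
        """Frame-by-frame EIM at B=1 reproduces the batched EIM rows."""
        net, plan = built_net
        x = random_input(plan, rng, batch=4)
        batched = net.run_eim(Tensor(x)).data
        for n in range(4):
            net.reset_states()
            out = None
            for t in range(plan.t_total):
                out = net.step_frame(Tensor(x[n : n + 1, t]))
            # BLAS may take a different summation path for a 1-row matmul,
            # so agreement is to rounding, not bitwise
            np.testing.assert_allclose(out.data[0], batched[n],
                                       rtol=1e-12, atol=1e-14)

    def test_single_timestep_is_feedforward(self, rng):
        plan = NetworkPlan(
            blocks=[BlockConfig(kind="conv2d_td", in_channels=1,
                                out_channels=2)],
            input_shape=(1, 4, 4), t_total=1, head=None,
            aggregation="last_step",
        )
        net = build_network(plan, seed=0)
        x = rng.normal(size=(2, 1, 1, 4, 4))
        out = net.run_eim(Tensor(x))
        ref, _ = net.blocks[0].step(Tensor(x[:, 0]), None)
        assert np.array_equal(out.data, ref.data)


class TestResetSemantics:
    def test_run_reset_run_reproduces_bitwise(self, built_net, rng):
        net, plan = built_net
        x = random_input(plan, rng)
        a = net.run_eim(Tensor(x)).data
        reset_states(net)
        b = net.run_eim(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_reset_is_idempotent(self, built_net, rng):
        net, plan = built_net
        x = random_input(plan, rng)
        net.run_eim(Tensor(x))
        net.reset_states()
        net.reset_states()
        assert net._states is None and net._acc is None

    def test_missing_reset_changes_output_and_is_detected(self, rng):
        """A neuron that retains potential makes the un-reset second run
        differ; with sample ids the runtime refuses the stale state."""
        plan = NetworkPlan(
            blocks=[BlockConfig(
                kind="fc_lif", in_channels=2, out_channels=2,
                neuron=NeuronParams(alpha=1.0, beta=0.0, v_th=1.5))],
            input_shape=(2,), t_total=2, head=None, aggregation="sum",
        )
        net = build_network(plan, seed=0)
        net.blocks[0].w.data = np.eye(2)
        x = np.full((1, 2, 2), 0.5)  # 2 steps of 0.5: sub-threshold in run 1
        first = net.run_eim(Tensor(x), reset=False, sample_id="a").data.copy()
        second = net.run_eim(Tensor(x), reset=False).data
        assert not np.array_equal(first, second)  # carried v crosses threshold
        with pytest.raises(StaleStateError):
            net.run_eim(Tensor(x), reset=False, sample_id="b")


class TestTemporalTransforms:
    def make_plan(self, kind, factor):
        return NetworkPlan(
            blocks=[
                BlockConfig(kind="conv_lif", in_channels=1, out_channels=2),
                BlockConfig(kind=kind, factor=factor),
                BlockConfig(kind="conv_lif", in_channels=2, out_channels=2),
            ],
            input_shape=(1, 4, 4), t_total=6, head=None, aggregation="sum",
        )

    @pytest.mark.parametrize("kind", ["subsample_t", "sumpool_t"])
    def test_second_block_sees_halved_time_axis(self, kind, rng):
        plan = self.make_plan(kind, 2)
        net = build_network(plan, seed=0)
        x = rng.normal(size=(1, 6, 1, 4, 4))
        seq = Tensor(x)
        seq = net.entries[0].forward_sequence(seq)
        from stp.network import _temporal_transform

        seq = _temporal_transform(seq, kind, 2)
        assert seq.shape[1] == 3
        out = net.run_iim(Tensor(x))
        assert np.isfinite(out.data).all()

    def test_eim_refuses_temporal_transforms(self):
        with pytest.raises(PlanError):
            NetworkPlan(
                blocks=[BlockConfig(kind="subsample_t", factor=2)],
                input_shape=(1, 4, 4), t_total=6, head=None, mode="eim",
            )
        plan = self.make_plan("subsample_t", 2)
        net = build_network(plan, seed=0)
        with pytest.raises(PlanError):
            net.run_eim(Tensor(np.zeros((1, 6, 1, 4, 4))))

    def test_indivisible_sumpool_rejected(self, rng):
        plan = self.make_plan("sumpool_t", 4)
        net = build_network(plan, seed=0)
        with pytest.raises(PlanError):
            net.run_iim(Tensor(rng.normal(size=(1, 6, 1, 4, 4))))


def test_wrong_t_rejected():
    plan = NetworkPlan(
        blocks=[BlockConfig(kind="fc_lif", in_channels=2, out_channels=2)],
        input_shape=(2,), t_total=3, head=None, aggregation="sum",
    )
    net = build_network(plan, seed=0)
    with pytest.raises(ContractError):
        net.run_iim(Tensor(np.zeros((1, 5, 2))))


def test_mismatched_plan_geometry_rejected():
    with pytest.raises(PlanError):
        build_network(NetworkPlan(
            blocks=[BlockConfig(kind="conv_lif", in_channels=3,
                                out_channels=2)],
            input_shape=(2, 4, 4), t_total=2, head=None,
        ), seed=0)
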