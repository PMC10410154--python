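import numpy as np
import pytest

from stp.blocks import BlockConfig
from stp.network import HeadSpec, NetworkPlan, build_network
from stp.synthetic import gen_synthetic_motion
from stp.training import TrainConfig, bptt_train, evaluate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def motion_plan(lifplus=None):
    """Small ConvLIF classifier for the 3-class moving-bar task."""
    return NetworkPlan(
        blocks=[
            BlockConfig(kind="conv_lif", in_channels=2, out_channels=8,
                        stride=(2, 2), lifplus=lifplus),
            BlockConfig(kind="conv_lif", in_channels=8, out_channels=16,
                        stride=(2, 2), lifplus=lifplus),
        ],
        input_shape=(2, 20, 20),
        t_total=20,
        head=HeadSpec(kind="linear", n_classes=3),
        aggregation="sum",
    )


def population_plan():
    """Deeper net ending in a population-coded FCLIF readout (7 per class)."""
    return NetworkPlan(
        blocks=[
            BlockConfig(kind="conv_lif", in_channels=2, out_channels=8,
                        stride=(2, 2), norm="batchnorm"),
            BlockConfig(kind="conv_lif", in_channels=8, out_channels=16,
                        stride=(2, 2), norm="batchnorm"),
            BlockConfig(kind="fc_lif", in_channels=400, out_channels=64,
                        norm="batchnorm"),
            BlockConfig(kind="fc_lif", in_channels=64, out_channels=21),
        ],
        input_shape=(2, 20, 20),
        t_total=20,
        head=HeadSpec(kind="population", n_classes=3, n_per_category=7),
        aggregation="mean",
    )


TRAIN_CFG = dict(optimizer="adam", lr=1e-3, weight_decay=1e-4,
                 batch_size=20, seed=0)


@pytest.fixture(scope="session")
def motion_data():
    train = gen_synthetic_motion(n_samples=200, seed=0)
    val = gen_synthetic_motion(n_samples=60, seed=1)
    return train, val


@pytest.fixture(scope="session")
def trained_lif(motion_data):
    """Default-LIF network trained on the motion task; shared baseline."""
    train, val = motion_data
    net = build_network(motion_plan(), seed=0)
    cfg = TrainConfig(epochs=15, **TRAIN_CFG)
    bptt_train(net, train, cfg)
    return net, evaluate(net, val)
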