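import numpy as np
import pytest
from hypothesis import settings

from phagoflow.fcs_io import SampleMeta
from phagoflow.gating import GateConfig, gate_sample
from phagoflow.synthetic_data import SynthConfig, simulate_sample

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sample():
    """One 10 000-event synthetic sample (infection group, day 0, 60 min,
    37 degC) with ground truth."""
    config = SynthConfig(seed=1, events_per_sample=10_000)
    meta = SampleMeta("p1", "infection", 0, 60, 37.0)
    table, truth = simulate_sample(config, meta)
    return config, table, truth


@pytest.fixture(scope="session")
def gated_sample(default_sample):
    config, table, truth = default_sample
    result = gate_sample(table, GateConfig(seed=1))
    return table, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
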