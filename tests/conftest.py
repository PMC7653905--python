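import logging

import numpy as np
import pytest

import trimorf as tm

# segment-placement warnings are expected on small simulated sets
logging.getLogger("trimorf.segmentation").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """40 simulated sequences with the default MoRF signal."""
    return tm.simulate_dataset(tm.SimConfig(n_sequences=40, seed=11))


@pytest.fixture(scope="session")
def trained_bundle(small_dataset):
    return tm.train_bundle(small_dataset, seed=11)


class ConstantModel:
    """Stand-in zone model returning a fixed score for every sample."""

    def __init__(self, value: float):
        self.value = value

    def normalized_scores(self, features):
        return np.full(len(features), self.value)


@pytest.fixture()
def stub_bundle():
    """Bundle whose terminal model scores 1.0 and middle model 0.0."""
    return tm.ModelBundle(
        terminal_model=ConstantModel(1.0),
        middle_model=ConstantModel(0.0),
        feature_config=tm.FeatureConfig(),
        svm_config=tm.SvmConfig(),
        flank=20,
    )


def make_trace(seq_id: str, n: int, seed: int = 0) -> tm.StructuralTrace:
    """A plausible full-channel trace of length n."""
    rng = np.random.default_rng(seed)
    ss = rng.gamma(2.0, 1.0, size=(n, 3))
    ss /= ss.sum(axis=1, keepdims=True)
    cols = {
        "SS_H": ss[:, 0], "SS_E": ss[:, 1], "SS_C": ss[:, 2],
        "ASA": rng.uniform(0, 1, n),
        "PHI": rng.uniform(-180, 180, n), "PSI": rng.uniform(-180, 180, n),
        "THETA": rng.uniform(0, 180, n), "TAU": rng.uniform(-180, 180, n),
        "HSEa_up": rng.normal(13, 3, n), "HSEa_dn": rng.normal(15, 4, n),
        "HSEb_up": rng.normal(12, 4, n), "HSEb_dn": rng.normal(16, 4, n),
        "CN": rng.normal(25, 6, n),
    }
    return tm.StructuralTrace(
        seq_id=seq_id, channels=tm.CHANNELS,
        values=np.column_stack([cols[c] for c in tm.CHANNELS]),
    )


@pytest.fixture()
def trace_factory():
    return make_trace
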