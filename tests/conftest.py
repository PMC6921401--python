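import numpy as np
import pandas as pd
import pytest

from suckletrack.data_model import FeatureTable, SampleMetadata
from suckletrack.simulate import (
    SimulationConfig,
    TransmittedOtuSpec,
    simulate_dataset,
)


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        {"s1": [5, 0, 3], "s2": [1, 2, 0], "s3": [0, 4, 4]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    return FeatureTable(counts)


@pytest.fixture
def tiny_metadata():
    rows = [
        dict(sample_id="s1", role="source", environment="milk", host_id="sowA",
             dyad_id="sowA", day=0, breed="landrace", sex=""),
        dict(sample_id="s2", role="source", environment="vagina", host_id="sowA",
             dyad_id="sowA", day=0, breed="landrace", sex=""),
        dict(sample_id="s3", role="sink", environment="jejunum", host_id="p1",
             dyad_id="sowA", day=3, breed="landrace", sex="female"),
    ]
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest dyad study reused across read-only tests."""
    cfg = SimulationConfig(
        n_dyads=4,
        n_features=120,
        days=(0, 3, 35),
        depth=3000,
        transmitted=TransmittedOtuSpec(n_planted=4, n_universal=1),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
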