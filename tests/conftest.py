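import numpy as np
import pytest

from ebcount import CountData, ModelDefinition, ReplicateStructure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_data():
    """4 samples (2 + 2), 6 tuples, equal library sizes."""
    counts = np.array(
        [
            [10, 12, 11, 9],
            [0, 0, 0, 0],
            [3, 5, 40, 52],
            [100, 90, 95, 110],
            [1, 0, 2, 1],
            [7, 9, 2, 1],
        ]
    )
    return CountData(counts=counts, lib_sizes=np.array([1000.0] * 4))


@pytest.fixture
def pairwise_models():
    return [
        ModelDefinition("A,B", [[0, 1, 2, 3]]),
        ModelDefinition("A|B", [[0, 1], [2, 3]]),
    ]


@pytest.fixture
def pairwise_reps():
    return ReplicateStructure([[0, 1], [2, 3]])
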