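import numpy as np
import pytest

from hdpmix.datatypes import MetabolomeMatrix, MicrobiomeCounts, MultiOmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    return MicrobiomeCounts(
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["t1", "t2", "t3", "t4"],
        values=np.array([[5, 0, 2, 1], [1, 1, 1, 4], [0, 3, 2, 2]]),
    )


@pytest.fixture
def tiny_metab():
    return MetabolomeMatrix(
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["m1", "m2"],
        values=np.array([[0.1, -1.2], [1.4, 0.3], [-0.5, 2.2]]),
    )


@pytest.fixture
def tiny_dataset(tiny_counts, tiny_metab):
    return MultiOmicsDataset(counts=tiny_counts, continuous=tiny_metab)
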