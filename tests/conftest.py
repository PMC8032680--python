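import numpy as np
import pytest

from smlmnet import PipelineConfig, SimulationSpec
from smlmnet.simulate import with_counts

SMALL_COUNTS = {"caveola": 2, "S2": 2, "S1B": 2, "S1A": 2}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A compact default scene: two blobs of each class, light background."""
    return with_counts(SimulationSpec(background_density_um3=1.0), SMALL_COUNTS)


@pytest.fixture
def config():
    return PipelineConfig()


def node_truth_labels(cloud, event_blob_labels):
    """Ground-truth blob label per merged node (majority over its events)."""
    src = cloud.source
    labels = np.zeros(len(cloud), dtype=int)
    for node in range(len(cloud)):
        vals, counts = np.unique(event_blob_labels[src == node],
                                 return_counts=True)
        labels[node] = vals[np.argmax(counts)]
    return labels
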