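import numpy as np
import pytest

from strokegcn.graph import SkeletonGraph, body_graph, body_racket_graph
from strokegcn.network import ModelConfig
from strokegcn.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def body():
    return body_graph()


@pytest.fixture(scope="session")
def body_racket():
    return body_racket_graph()


@pytest.fixture
def path3():
    """Path graph on 3 nodes with a hand-checkable normalization."""
    O = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return SkeletonGraph.from_adjacency(("a", "b", "c"), O)


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(gcn_hidden=2, gcn_out=2, rnn_hidden=3, head_hidden=3,
                       center=False)


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Small zero-noise corpus shared by the slower training tests."""
    cfg = SynthConfig(counts=(8, 8, 8, 8), noise_sd=0.0,
                      duration_range=(25, 40), seed=3, n_left_handed=0)
    return generate_dataset(cfg)
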