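import numpy as np
import pytest

from echocount import EchogramSpec, synthesize_echogram


@pytest.fixture(scope="session")
def default_scene():
    """One synthetic echogram with well-separated fish, shared across tests."""
    spec = EchogramSpec(n_fish=10, seed=7, min_separation_px=30)
    echo, truth = synthesize_echogram(spec)
    return spec, echo, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
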