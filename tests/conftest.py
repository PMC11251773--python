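import numpy as np
import pytest

from lanthimine import pipeline, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory):
    """A generated synthetic genome bundle shared across tests (seed 1)."""
    out = tmp_path_factory.mktemp("synth")
    cfg = synthdata.SynthConfig(seed=1)
    truth = pipeline.run_synth(cfg, out)
    return {"dir": out, "config": cfg, "truth": truth}
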