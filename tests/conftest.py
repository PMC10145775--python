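import numpy as np
import pytest

from gaitring import pipeline, synthetic


SHORT_SEQUENCE = (
    ("W1", 30.0),
    ("A1", 8.0),
    ("W2", 20.0),
    ("A3", 10.0),
    ("A5", 12.0),
)


@pytest.fixture(scope="session")
def default_knobs():
    return synthetic.GaitKnobs()


@pytest.fixture(scope="session")
def short_config():
    """An 80 s protocol for tests that do not need the full 6 min."""
    return synthetic.ProtocolConfig(
        regime_sequence=SHORT_SEQUENCE, total_duration_s=80.0, seed=11
    )


@pytest.fixture(scope="session")
def short_annotated(short_config, default_knobs):
    return synthetic.generate_protocol(short_config, default_knobs)


@pytest.fixture(scope="session")
def default_annotated(default_knobs):
    """One full-length default protocol recording."""
    return synthetic.generate_protocol(synthetic.ProtocolConfig(seed=3), default_knobs)


@pytest.fixture(scope="session")
def prepared_default(default_annotated):
    """(filtered recording, spectral series) of the default recording."""
    return pipeline.prepare(default_annotated.recording)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
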