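import numpy as np
import pytest

from seqssvep import stimgen, synthgen


@pytest.fixture(scope="session")
def vbar_spec():
    """Canonical 14-section vertical-bar stimulus at 144 Hz, 50 trials."""
    return stimgen.StimulusSpec("vertical_bars", n_sections=14, refresh_hz=144.0)


@pytest.fixture(scope="session")
def short_schedule():
    """Small sequential schedule (5 trials) shared across synthetic tests."""
    spec = stimgen.StimulusSpec("vertical_bars", n_sections=14, refresh_hz=144.0,
                                n_trials=5)
    return stimgen.build_sequential_schedule(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth_config():
    return synthgen.SyntheticConfig(n_channels=12, hf_span_channels=(4, 7),
                                    rng_seed=99)
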