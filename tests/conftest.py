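import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def linear_trace():
    """Noiseless linear-response trace with a known complex modulus."""
    from oscdrop import TraceRecipe, generate_oscillation_trace

    recipe = TraceRecipe(
        frequency=0.05,
        modulus=30.0 + 10.0j,
        amplitude_fraction=0.1,
        noise_sd=0.0,
        duration_periods=10,
        sample_rate=2.0,
    )
    return generate_oscillation_trace(recipe), 30.0 + 10.0j
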