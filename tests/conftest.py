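import numpy as np
import pytest

from emgait.synthetic import (GaitCycleSpec, generate_recording,
                              well_separated_profiles)


@pytest.fixture(scope="session")
def small_recording():
    """8-channel well-separated recording, 10 cycles, deterministic."""
    spec = GaitCycleSpec(cycle_duration=1.1, n_cycles=10)
    return generate_recording(well_separated_profiles(), spec,
                              noise_sd=0.05, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
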