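import numpy as np
import pytest
from hypothesis import settings

import ivivc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_buffered_dataset():
    """215 min fasted-state run of the buffered crystalline preset."""
    return ivivc.simulate_transit(
        ivivc.default_method(), ivivc.buffered_crystal()
    )


@pytest.fixture(scope="session")
def truncated_nonbuffered_dataset():
    """43 min run of the nonbuffered amorphous preset."""
    return ivivc.simulate_transit(
        ivivc.truncated_method(), ivivc.nonbuffered_amorphous()
    )


@pytest.fixture(scope="session")
def synthetic_pk_profile():
    """Synthetic mean oral plasma curve with an early peak."""
    times = np.arange(0.0, 12.0 + 1e-9, 0.25)
    return ivivc.generate_synthetic_pk(ivivc.OralPKParams(), times)
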