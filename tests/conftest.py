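import numpy as np
import pytest

from dyadsync.simulate import SimConfig, generate_classroom


@pytest.fixture(scope="session")
def small_classroom():
    """One room, two dyads, 10-minute session, both channels."""
    cfg = SimConfig(n_rooms=1, dyads_per_room=2, session_len=600,
                    event_rate=1.0, seed=7)
    return generate_classroom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
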