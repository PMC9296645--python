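import numpy as np
import pytest
from hypothesis import settings

import slowwave as sw
from slowwave.scoring import Hypnogram

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def short_spec():
    """Six-minute default-parameter synthetic spec (quick unit-test fixture)."""
    return sw.SyntheticSpec(total_hours=0.1, noise_seed=42)


@pytest.fixture(scope="session")
def two_hour_recording():
    """Two hours of default synthetic data with its ground-truth hypnogram."""
    spec = sw.SyntheticSpec(total_hours=2.0, noise_seed=7)
    hyp = sw.generate_hypnogram(spec)
    rec = sw.generate_recording(hyp, spec)
    return spec, hyp, rec


def all_state_hypnogram(state: str, n_epochs: int, epoch_len_s: float = 5.0) -> Hypnogram:
    return Hypnogram(
        states=np.array([state] * n_epochs, dtype=object), epoch_len_s=epoch_len_s
    )
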