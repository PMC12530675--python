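import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aforg import OrganizationSpec, Recording, generate_atrial_train, render_electrogram
from aforg.synthetic import _rng

FS = 250.0  # analysis sampling rate used throughout the suite


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_egm_recording(
    theta: float,
    seed_key: tuple,
    duration_s: float = 50.0,
    fs: float = FS,
    channel: str = "CS1-2",
    phase: str = "pre",
    **spec_kw,
) -> Recording:
    """One-channel synthetic electrogram recording for entropy tests."""
    spec = OrganizationSpec(theta=theta, **spec_kw)
    train = generate_atrial_train(spec, duration_s, rng=_rng(*seed_key, 0))
    trace = render_electrogram(train, spec, fs=fs, rng=_rng(*seed_key, 1))
    return Recording(
        signals={channel: trace}, fs=fs, patient_id="T", phase=phase,
        pvi_completion=1.0,
    )


@pytest.fixture(scope="session")
def warm_kernel():
    """Trigger numba compilation once so timings elsewhere are clean."""
    from aforg import sample_entropy

    sample_entropy(np.sin(np.arange(50.0)), m=2, r_abs=0.2)
    sample_entropy(np.sin(np.arange(50.0)), m=3, r_abs=0.2)
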