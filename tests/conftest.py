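import numpy as np
import pytest

import spikecl as scl


@pytest.fixture(scope="session")
def templates():
    return scl.make_templates(2, m=64, seed=0)


@pytest.fixture(scope="session")
def clean_recording(templates):
    """Noise-free 2-unit recording with ground truth."""
    spec = scl.SimulationSpec(snr_db=np.inf, duration_s=5.0, seed=11)
    return scl.generate_recording(spec, templates)


@pytest.fixture(scope="session")
def noisy_recording(templates):
    """Default-condition 8 dB recording with ground truth."""
    spec = scl.SimulationSpec(snr_db=8.0, duration_s=10.0, seed=7)
    return scl.generate_recording(spec, templates)


@pytest.fixture(scope="session")
def overlapping_clouds():
    """Moderately overlapping 2-cluster feature set (3.5 sd separation)."""
    d = 3.5 / np.sqrt(2)
    return scl.feature_cloud(1000, [(0.0, 0.0), (d, d)], 1.0, seed=42)
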