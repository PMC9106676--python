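import numpy as np
import pytest

from cuffbp.io import WaveformRecord
from cuffbp.simulate import SimulationParams, render_recording


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless 2-min sitting-only session: every fiducial is exact."""
    return SimulationParams(
        duration=120.0,
        seed=11,
        noise_scale=0.0,
        pat_jitter_sd=0.0,
        amplitude_jitter=0.0,
        sbp_sd=6.0,
        activity_schedule=[("sitting", 0.0, 120.0)],
        train_sweep_mmhg=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_params):
    return render_recording(clean_params)


@pytest.fixture(scope="session")
def noisy_recording():
    """10-min session with default noise/artifact levels and mixed activity."""
    return render_recording(SimulationParams(duration=600.0, seed=12))


@pytest.fixture()
def tiny_record():
    rng = np.random.default_rng(0)
    return WaveformRecord(
        subject_id="t",
        fs=64.0,
        ecg=rng.normal(size=256),
        ppg=rng.normal(size=256),
        bp=80.0 + 20.0 * rng.random(256),
        activity=np.array(["sitting"] * 128 + ["walking"] * 128, dtype=object),
    )
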