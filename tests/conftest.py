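import warnings

import numpy as np
import pytest

import boldphysio as bp


@pytest.fixture(scope="session")
def scenario404():
    """A single-subject scenario at full scan length (404 volumes, TR 1.4 s)."""
    return bp.SimScenario(seed=11, n_vols=404, tr_s=1.4, physio_fs_hz=25.0)


@pytest.fixture(scope="session")
def timecourses404(scenario404):
    return bp.simulate_timecourses(scenario404, "young01")


@pytest.fixture(scope="session")
def joint_design404(scenario404, timecourses404):
    return bp.build_regressors(
        timecourses404, "joint", scenario404.tr_s, scenario404.n_vols
    )


@pytest.fixture()
def quiet():
    """Silence expected runtime warnings inside a test body."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def pulse_train(freq_hz: float, duration_s: float, fs: float) -> bp.PhysioRecording:
    """Raised-cosine pulse train used as a synthetic PPG."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    period = 1.0 / freq_hz
    phase = (t % period) / 0.4
    ppg = np.where(phase < 1.0, 0.5 * (1 - np.cos(2 * np.pi * phase)), 0.0)
    return bp.PhysioRecording(ppg, fs, "ppg")
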