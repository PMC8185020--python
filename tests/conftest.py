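import numpy as np
import pytest

from rtnf.paradigm import build_parallel_schedule, build_serial_schedule
from rtnf.synthetic import SimulationParams, simulate_roi_run


@pytest.fixture(scope="session")
def parallel():
    return build_parallel_schedule(tr=2.0)


@pytest.fixture(scope="session")
def serial():
    return build_serial_schedule(tr=2.0)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free 2% think activation in the target ROI only."""
    return SimulationParams(
        amplitudes={"target": {"think": 2.0}, "background": {}},
        noise_sd=0.0, drift_amplitude=0.0, global_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_serial_run(serial, clean_params):
    return simulate_roi_run(serial, clean_params, seed=7)


@pytest.fixture(scope="session")
def clean_parallel_run(parallel, clean_params):
    return simulate_roi_run(parallel, clean_params, seed=7)


@pytest.fixture(scope="session")
def noise_params():
    """Null simulation parameters with serially correlated noise only."""
    return SimulationParams(
        amplitudes={"target": {}, "background": {}},
        noise_sd=0.5, drift_amplitude=0.0, global_sd=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
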