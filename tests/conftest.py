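import numpy as np
import pytest

from fmriscrub.simulate import SimulationConfig, simulate_dataset
from fmriscrub.types import MotionTrace, ROITimeSeries


@pytest.fixture(scope="session")
def small_dataset():
    """A small contaminated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_scans=12, n_roi=15, frames=120, seed=123)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Artifact-free, covariate-free dataset (pure network + noise)."""
    cfg = SimulationConfig(
        n_scans=12, n_roi=15, frames=120, seed=321,
        artifact_gain=0.0, ga_effect=0.0, sex_effect=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_motion(rng, frames=50, scale=0.5, tr=3.0) -> MotionTrace:
    return MotionTrace(params=rng.normal(0, scale, (frames, 6)), tr_seconds=tr)


def random_timeseries(rng, frames=60, n_roi=5, tr=3.0) -> ROITimeSeries:
    return ROITimeSeries(
        data=rng.standard_normal((frames, n_roi)),
        roi_ids=[f"r{i}" for i in range(n_roi)],
        tr_seconds=tr,
    )
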