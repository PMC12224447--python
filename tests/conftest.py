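import numpy as np
import pytest

from vamkit import AcquisitionParams, RunConfig, VoxelTruth


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def config(acq) -> RunConfig:
    return RunConfig(acq=acq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240111)


@pytest.fixture
def clean_truth() -> VoxelTruth:
    """Noise- and leakage-free voxel with the spin echo peaking first."""
    return VoxelTruth(noise_sd=0.0)
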