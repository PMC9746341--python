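import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hippomrs.synthdata import (
    AcquisitionParams,
    CohortSpec,
    GroundTruthSpectrum,
    PhantomSpec,
    generate_cohort,
    generate_fid,
    generate_phantom_volume,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruthSpectrum(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_truth():
    return GroundTruthSpectrum(noise_sd=80.0)


@pytest.fixture(scope="session")
def noiseless_fid_pair(noiseless_truth, acq):
    return generate_fid(noiseless_truth, acq, seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom (fast to scan exhaustively) with one ellipsoid pair."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        hippocampus_ellipsoids=(
            ((-9.0, 0.0, 0.0), (5.0, 6.0, 7.0)),
            ((9.0, 0.0, 0.0), (5.0, 6.0, 7.0)),
        ),
    )
    return generate_phantom_volume(spec)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=42))


def amp_vector(truth):
    """Ground-truth amplitudes in the fitting model's peak order."""
    order = ["naa", "tcho", "tcr", "glx", "ins"]
    return np.array([truth.amplitudes[m] for m in order])
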