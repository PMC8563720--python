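import numpy as np
import pytest

from flimfret.models import AcquisitionConfig, Irf
from flimfret.phantom import PhantomConfig


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def delta_irf(acq) -> Irf:
    return Irf.delta(acq.n_bins, acq.bin_width)


@pytest.fixture(scope="session")
def gauss_irf(acq) -> Irf:
    return Irf.gaussian(acq.n_bins, acq.bin_width)


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """Scaled-down phantom for fast unit tests."""
    return PhantomConfig(
        image_size=(96, 96),
        n_foci={"early": 40, "mid": 15, "late": 10},
    )


def poisson_decay(expected: np.ndarray, seed: int) -> np.ndarray:
    """Shared helper: one Poisson realization of an expected decay."""
    return np.random.default_rng(seed).poisson(expected).astype(float)
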