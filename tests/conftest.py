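import numpy as np
import pytest

from enf3d import (BoxWindow, MarkovZParams, generate_base_points,
                   generate_sample, healthy_like_group)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def biopsy_window():
    """The standard 320 x 432 x 100 μm observation box."""
    return BoxWindow.from_extents(320.0, 432.0, 100.0)


def make_csr(rng, n, window):
    """Binomial (fixed-n) CSR pattern in a 2D or 3D box."""
    lo, hi = window.lower, window.upper
    return rng.uniform(lo, hi, size=(n, window.ndim))


@pytest.fixture(scope="session")
def small_sample(biopsy_window):
    """One healthy-like synthetic sample with a short generation chain,
    reused by pattern/IO/summary tests that only need a realistic pattern."""
    return generate_sample(
        healthy_like_group(), biopsy_window, seed=7,
        labels={"group": "healthy", "subject": "healthy-s1",
                "sample": "healthy-s1-k1"},
        mcmc_burn_in=300, mcmc_sweeps=100,
    )


@pytest.fixture(scope="session")
def clustered_ends(small_sample):
    """End-point coordinates of the reusable synthetic sample."""
    return small_sample.points_of("end")
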