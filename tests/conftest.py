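import numpy as np
import pytest

from metastim import (
    CueConflictConfig,
    SurfaceOrientation,
    normal_from_orientation,
)
from metastim.experiment_design import judgment_design


@pytest.fixture(scope="session")
def design():
    return judgment_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cue_pair(rng, min_sep_deg=5.0, max_slant=55.0):
    """Random non-parallel texture/disparity normal pair."""
    while True:
        s1, s2 = rng.uniform(1.0, max_slant, 2)
        t1, t2 = rng.uniform(0.0, 360.0, 2)
        n_t = normal_from_orientation(SurfaceOrientation(s1, t1))
        n_d = normal_from_orientation(SurfaceOrientation(s2, t2))
        dot = float(n_t @ n_d)
        if dot < np.cos(np.deg2rad(min_sep_deg)):
            return n_t, n_d


def random_inplane_percept(rng, n_t, n_d):
    """Unit vector in span(n_t, n_d), not necessarily inside the wedge."""
    alpha = rng.uniform(-0.3, 1.3)
    v = alpha * n_t + (1.0 - alpha) * n_d
    return v / np.linalg.norm(v)


@pytest.fixture
def conflict_config():
    return CueConflictConfig(sigma_c=25.0, tau_c=45.0, delta_sigma=30.0, delta_tau=45.0)
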