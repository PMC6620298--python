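import warnings

import numpy as np
import pytest

from microbeam.classify import Thresholds
from microbeam.cohort import CohortConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_calibration_warnings():
    # cohort G' ranges deliberately exceed the two-anchor calibration span;
    # the extrapolation warning is expected and not under test here
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=r"sigma_y\(G'\)")
        warnings.filterwarnings("ignore", message=r"E\(collagen\)")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """500-beam cohort at the study's default conditions, seed 42."""
    cfg = CohortConfig(n_beams=500, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_thresholds():
    return Thresholds()
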