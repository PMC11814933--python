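import numpy as np
import pytest

from neglectprog.engine import CVPlan, reduced_grid
from neglectprog.pipeline import CohortAnalysis
from neglectprog.simulate import CohortConfig, generate_cohort, plant_roi

#: Study conditions for the planted-outcome cohort used across the suite:
#: chronic outcome loads on acute severity + ROI overlap only.
PLANTED_CONFIG = CohortConfig(seed=11, effect_weights=(0.65, 0.35, 0.0), noise_sd=0.05)


@pytest.fixture(scope="session")
def planted_cohort():
    """One 12/30/30 cohort with a known acute + ROI generative structure."""
    patients, lesions, gt = generate_cohort(PLANTED_CONFIG)
    roi = plant_roi(PLANTED_CONFIG.grid_shape, PLANTED_CONFIG.roi_spec, PLANTED_CONFIG.affine)
    return patients, lesions, gt, roi


@pytest.fixture(scope="session")
def analysis(planted_cohort):
    patients, lesions, _, roi = planted_cohort
    return CohortAnalysis(patients, lesions, roi)


@pytest.fixture(scope="session")
def quick_plan():
    """Reduced profile: 5x5 grid, 2 repetitions."""
    return CVPlan(grid=tuple(reduced_grid()), n_repetitions=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
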