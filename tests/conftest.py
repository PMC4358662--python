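import numpy as np
import pytest

import flydev as f


@pytest.fixture(scope="session")
def default_truth():
    return f.SimulationTruth(seed=7)


@pytest.fixture(scope="session")
def default_obs(default_truth):
    """One simulated cohort under the stated truth and truth-derived design."""
    design = f.schedule_from_truth(default_truth)
    return f.simulate_cohort(default_truth, design)


@pytest.fixture(scope="session")
def default_points(default_obs):
    points, _ = f.transition_points(default_obs)
    return points


@pytest.fixture(scope="session")
def linear_truth():
    """Noise-free linear thermal-summation world: t_min 10 degC, E-A 230 degC day."""
    return f.SimulationTruth(
        stage_add={"E-L1": 8.2, "E-L2": 21.3, "E-L3f": 35.2, "E-L3m": 82.5,
                   "E-P": 107.5, "E-A": 230.0},
        t_min=10.0, curvature_low=1.0, curvature_high=1.0,
        cv_transition=1e-12, mortality={}, seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
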