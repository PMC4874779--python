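import numpy as np
import pytest

from ime.bmi import BMIMapping
from ime.simulate import MismatchSpec, SessionSpec, make_ground_truth, simulate_session

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_spec():
    """Small but realistic task spec used across tests."""
    return SessionSpec(n_units=12, trials_per_target=3, n_targets=8)


@pytest.fixture(scope="session")
def matched_session(small_spec):
    """Session whose subject's internal model is decoder-equivalent (no mismatch)."""
    gt = make_ground_truth(small_spec, MismatchSpec(), seed=1)
    return gt, simulate_session(gt, small_spec, seed=1)


@pytest.fixture(scope="session")
def rotated_session(small_spec):
    """Session with a 30-degree internal-model rotation mismatch."""
    gt = make_ground_truth(small_spec, MismatchSpec(rotation=30.0), seed=2)
    return gt, simulate_session(gt, small_spec, seed=2)


@pytest.fixture
def tiny_mapping():
    rng = np.random.default_rng(7)
    Bv = rng.standard_normal((2, 3))
    return BMIMapping(Bv, rng.standard_normal(2), dt=0.033, smooth_window=5)
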