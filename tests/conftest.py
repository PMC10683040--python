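import numpy as np
import pytest

from heartcac import phantom

# Validation-cohort risk-category confusion table (rows = ground truth).
TABLE2A = np.array([
    [115, 15, 9, 0, 0],
    [0, 38, 5, 0, 0],
    [0, 0, 84, 2, 0],
    [0, 0, 1, 71, 2],
    [0, 0, 0, 0, 67],
])


@pytest.fixture(scope="session")
def demo_spec():
    """Three-lesion phantom with two non-coronary distractors."""
    geo = phantom.DEFAULT_DISTRACTOR_GEOMETRY
    return phantom.PhantomSpec(
        lesions=(
            phantom.Lesion(vessel=2, t=0.45, radius_mm=3.0, hu=450.0),
            phantom.Lesion(vessel=4, t=0.30, radius_mm=2.2, hu=250.0),
            phantom.Lesion(vessel=3, t=0.70, radius_mm=2.6, hu=320.0),
        ),
        distractors=(
            phantom.Distractor("aortic", *geo["aortic"]),
            phantom.Distractor("pericardial", *geo["pericardial"]),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_scan(demo_spec):
    return phantom.make_scan(demo_spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Six randomized phantoms shared across tests."""
    return phantom.simulate_dataset(6, seed=7, distractor_rate=0.5)
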