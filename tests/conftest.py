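import numpy as np
import pytest

import spinemorph as sm


@pytest.fixture(scope="session")
def default_cohort():
    """One full 24-subject cohort with images (shared across tests)."""
    cfg = sm.CohortConfig(seed=7)
    samples, subjects, truth = sm.generate_cohort(cfg)
    return cfg, samples, subjects, truth


@pytest.fixture(scope="session")
def shapes_cohort():
    """Shapes-only cohort (single level/muscle) for fast shape-statistics tests."""
    cfg = sm.CohortConfig(
        seed=11, levels=("S1",), muscles=("MF",), generate_images=False
    )
    subjects, contours, truth = sm.generate_cohort_shapes(cfg)
    return cfg, subjects, contours, truth


def random_contour(rng, r0=10.0, center=(50.0, 50.0), K=64):
    """A valid random star-shaped contour for property tests."""
    a = 0.05 * rng.standard_normal(4)
    b = 0.05 * rng.standard_normal(4)
    return sm.synth_contour(r0, a, b, center, K)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
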