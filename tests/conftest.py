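import numpy as np
import pandas as pd
import pytest

from ketodetect import HEALTHY, SICK
from ketodetect.feature_classifier import FEATURE_NAMES
from ketodetect.io import bundle_from_cohort
from ketodetect.synthetic import CohortSpec, apply_missingness, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest fully observed cohort used by several module tests."""
    return generate_cohort(CohortSpec(n_animals=120, seed=11))


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return bundle_from_cohort(apply_missingness(small_cohort, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_feature_table(n=40, n_informative=1, shift=3.0, seed=0):
    """Features: the first `n_informative` separate the classes, rest noise."""
    r = np.random.default_rng(seed)
    y = np.array([SICK] * (n // 2) + [HEALTHY] * (n - n // 2))
    cols = {}
    for i, name in enumerate(FEATURE_NAMES):
        base = r.normal(0.0, 1.0, n)
        if i < n_informative:
            base = base + shift * (y == SICK)
        cols[name] = base
    return pd.DataFrame(cols), y
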