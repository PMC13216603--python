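"""Shared fixtures: small synthetic cohorts and bags for fast unit tests."""

import numpy as np
import pytest

from caremil.bag_store import InstanceBag
from caremil.synth_gen import CohortConfig, generate_cohort_bags


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A miniature cohort: low dim, few patients, small slides — fast to
    generate and train on, but with the same disease structure."""
    return CohortConfig(dim=16, n_patients_per_class=12,
                        cells_per_slide_range=(80, 120), seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    records, bags, type_model = generate_cohort_bags(tiny_cohort_config)
    return records, bags, type_model


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_bag(rng):
    X = rng.normal(size=(12, 8))
    return InstanceBag("bag0", X, [f"c{i}" for i in range(12)],
                       cell_types=["A", "B", "C"] * 4)
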