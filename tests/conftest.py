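import numpy as np
import pytest

from huimin_hcm.design import (
    LINEAR,
    DUMMY,
    Attribute,
    AttributeDictionary,
    default_attributes,
    generate_design,
)
from huimin_hcm.preprocess import filter_dataset
from huimin_hcm.simulate import default_true_params, simulate_survey


@pytest.fixture(scope="session")
def attrs():
    return default_attributes()


@pytest.fixture(scope="session")
def toy_attrs():
    """Two small linear attributes with opposite-signed levels so that
    incomparable (trade-off) pairs exist."""
    return AttributeDictionary(
        (
            Attribute("a", (0.0, 1.0), LINEAR, "+"),
            Attribute("b", (0.0, 1.0, 2.0), LINEAR, "+"),
        )
    )


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def study_design(attrs):
    return generate_design(attrs, n_sets=24, n_blocks=4, seed=11, n_restarts=1)


@pytest.fixture(scope="session")
def small_dataset(study_design, true_params):
    return simulate_survey(study_design, true_params, n=120,
                           inattentive_fraction=10 / 120, seed=3)


@pytest.fixture(scope="session")
def filtered_small(small_dataset):
    filtered, _ = filter_dataset(small_dataset)
    return filtered
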