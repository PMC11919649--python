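import numpy as np
import pytest

from impulsed import TwoCompartmentModel, default_protocol
from impulsed.synthetic_cohort import (CohortSpec, apply_exclusions,
                                       cohort_table, generate_roster)

COHORT_SEED = 17


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def model(protocol):
    return TwoCompartmentModel(protocol)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def default_cohort(default_spec, model):
    """Truth-level cohort table for the default composition at the test seed."""
    roster = generate_roster(default_spec, seed=COHORT_SEED)
    enrolled, _ = apply_exclusions(roster)
    return cohort_table(enrolled, model)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down composition for pipeline/CLI tests."""
    return CohortSpec(
        n_collected=60,
        exclusions={"small_lesion": 2, "no_pathology": 1, "poor_quality": 1},
        n_benign=26,
        n_malignant=30,
        benign_histology={"fibroadenoma": 26},
        malignant_histology={"invasive_carcinoma": 25, "lymphoma": 5},
        er_pos=15, pr_pos=12, her2_pos=8, ki67_high=20,
        grades={"I": 1, "II": 14, "III": 10},
        subtypes={"LuminalA": 4, "LuminalB": 10, "HER2over": 6, "TN": 5},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
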