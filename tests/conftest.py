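import numpy as np
import pytest

from pmfscreen.cohort import windows_from_cohort
from pmfscreen.constants import DEFAULT_PHENOTYPE_MAPPING
from pmfscreen.features import build_feature_matrix, load_phewas_mapping
from pmfscreen.simulate import CohortConfig, generate_cohort, patients_frame


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic desk-scale cohort shared across tests."""
    cfg = CohortConfig(n_unlabeled=300, n_labeled_positive=30, hidden_positive_rate=0.05, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    windows = windows_from_cohort(small_cohort)
    demo = patients_frame(small_cohort)[["patient_id", "birth_year", "gender"]]
    return build_feature_matrix(
        windows,
        demographics=demo,
        mapping=load_phewas_mapping(DEFAULT_PHENOTYPE_MAPPING),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
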