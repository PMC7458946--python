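import numpy as np
import pandas as pd
import pytest

from cifrisk import CIFS, GeneratorConfig, generate_dataset
from cifrisk.features import build_feature_matrix, default_feature_specs


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset (~700 activities)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    ds = default_dataset
    return build_feature_matrix(ds.activities, ds.studies, ds.sites,
                                default_feature_specs())


@pytest.fixture(scope="session")
def null_config():
    """Generator configuration with every true coefficient zeroed."""
    return GeneratorConfig(seed=11, true_coefficients={c: {} for c in CIFS})


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def tiny_tables():
    """Minimal hand-written activities/studies/sites triple."""
    studies = pd.DataFrame({
        "study_id": ["S1", "S2"],
        "phase": ["I", "III"],
        "therapeutic_area": ["oncology", "autoimmune"],
        "randomized": [True, False],
        "design": ["parallel", "single_group"],
        "pediatric": [False, True],
    })
    sites = pd.DataFrame({
        "site_id": ["S1-A", "S1-B", "S2-A", "S2-B"],
        "study_id": ["S1", "S1", "S2", "S2"],
        "country": ["US", "CH", "US", "DE"],
        "patients_enrolled": [10, 33, 40, 5],
        "screen_failure_rate": [0.5, 0.7, 0.1, 0.62],
        "active_screening_days_per_enrolled": [12.0, 40.0, 8.0, 30.0],
        "parallel_trials_same_ta": [0, 2, 2, 5],
        "ae_reporting_latency_days": [1.0, 5.0, 0.5, 3.0],
    })
    activities = pd.DataFrame({
        "activity_id": ["A1", "A2", "A3", "A4"],
        "year": [2011, 2011, 2012, 2012],
        "activity_type": ["audit", "audit", "inspection", "audit"],
        "study_id": ["S1", "S1", "S2", "S2"],
        "site_id": ["S1-A", "S1-B", "S2-A", "S2-B"],
        **{f"finding_{c}": [0, 1, 2, 0] for c in CIFS},
    })
    return activities, studies, sites


@pytest.fixture
def tiny_triple():
    return tiny_tables()
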