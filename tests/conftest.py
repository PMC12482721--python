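import pandas as pd
import pytest

import pars_reach as pr
from pars_reach.synthetic import SyntheticConfig, generate_extract

# The 18 ICD-10-CM asthma codes, with the published truncation decision:
# moderate (J45.4x) and severe (J45.5x) persistent asthma are exclusionary,
# every other severity is not.
ASTHMA_CODES = [
    ("J45.20", "Mild intermittent asthma, uncomplicated", None),
    ("J45.21", "Mild intermittent asthma with (acute) exacerbation", None),
    ("J45.22", "Mild intermittent asthma with status asthmaticus", None),
    ("J45.30", "Mild persistent asthma, uncomplicated", None),
    ("J45.31", "Mild persistent asthma with (acute) exacerbation", None),
    ("J45.32", "Mild persistent asthma with status asthmaticus", None),
    ("J45.40", "Moderate persistent asthma, uncomplicated", "J45.4*"),
    ("J45.41", "Moderate persistent asthma with (acute) exacerbation", "J45.4*"),
    ("J45.42", "Moderate persistent asthma with status asthmaticus", "J45.4*"),
    ("J45.50", "Severe persistent asthma, uncomplicated", "J45.5*"),
    ("J45.51", "Severe persistent asthma with (acute) exacerbation", "J45.5*"),
    ("J45.52", "Severe persistent asthma with status asthmaticus", "J45.5*"),
    ("J45.901", "Unspecified asthma with (acute) exacerbation", None),
    ("J45.902", "Unspecified asthma with status asthmaticus", None),
    ("J45.909", "Unspecified asthma, uncomplicated", None),
    ("J45.990", "Exercise induced bronchospasm", None),
    ("J45.991", "Cough variant asthma", None),
    ("J45.998", "Other asthma", None),
]


@pytest.fixture(scope="session")
def asthma_universe():
    return {pr.normalize_code(raw) for raw, _, _ in ASTHMA_CODES}


@pytest.fixture(scope="session")
def inclusion_set():
    return pr.bundled_inclusion()


@pytest.fixture(scope="session")
def exclusion_set():
    return pr.bundled_exclusion()


@pytest.fixture(scope="session")
def criteria_set():
    return pr.bundled_criteria()


@pytest.fixture(scope="session")
def small_extract(criteria_set):
    """A small but structurally complete synthetic extract."""
    return generate_extract(SyntheticConfig(seed=42, n_patients=500), criteria_set)


def make_visits(rows):
    return pd.DataFrame(rows, columns=["visit_id", "patient_id", "clinic_id",
                                       "provider_id", "service_date", "age_at_visit"]).astype(str)


def make_dx(rows):
    return pd.DataFrame(rows, columns=["visit_id", "source", "code"]).astype(str)


def make_refs(rows):
    return pd.DataFrame(rows, columns=["visit_id", "referral_code"]).astype(str)
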