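import pandas as pd
import pytest

from perilink import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-mother cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_mothers=200, seed=11))


@pytest.fixture()
def births_two_mothers():
    """Hand-written births table: one single-birth and one two-birth mother."""
    return pd.DataFrame(
        {
            "PPN_mum": ["M1", "M2", "M2"],
            "PPN_baby": ["B1", "B2a", "B2b"],
            "BirthOrder": [1, 1, 2],
            "AgeBirthMum": [10000, 9000, 9700],
            "GageWeeks": [40, 38, 40],
            "Cob": ["AUS", "NZ", "MISSING"],
            "SmokingPreg": ["N", "Y", "Y"],
            "Birthweight": [3400, 3100, 3600],
        }
    )
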