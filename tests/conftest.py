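import numpy as np
import pandas as pd
import pytest

from cogineq import AgeZScorer, GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def survey_2000():
    """Medium synthetic round emulating the 2000 survey, no missingness."""
    return generate_survey(GeneratorConfig(n_children=4000, seed=42))


@pytest.fixture(scope="session")
def survey_2007():
    return generate_survey(GeneratorConfig(n_children=4000, seed=43, round_label="2007"))


@pytest.fixture(scope="session")
def zscored_2000(survey_2000):
    return AgeZScorer().fit(survey_2000).transform(survey_2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231030)


@pytest.fixture()
def tiny_table():
    """Hand-sized two-round table with known values."""
    return pd.DataFrame(
        {
            "raw_score": [3, 5, 7, 9, 4, 6, 8, 10],
            "age": [7, 7, 8, 8, 7, 7, 8, 8],
            "log_pce": [11.0, 11.5, 12.0, 12.5, 11.2, 11.7, 12.2, 12.7],
            "weight": [1.0] * 8,
            "round": ["2000"] * 4 + ["2007"] * 4,
        }
    )
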