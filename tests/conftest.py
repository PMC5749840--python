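import warnings

import pandas as pd
import pytest

from lomaspulse.survey_io import build_survey_table
from lomaspulse.synthetic_data import SimulationConfig, fixture_small, simulate_survey


@pytest.fixture()
def small_table():
    return fixture_small()


@pytest.fixture(scope="session")
def sim_default():
    """One full-size simulated survey shared across tests (seed fixed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_survey(SimulationConfig(seed=42))


def make_table(rows, roster=None):
    """Build a SurveyTable from (campaign, date, plot, zone, species, n, cover)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "campaign_id",
            "date",
            "plot_id",
            "zone",
            "species",
            "abundance",
            "cover_cm2",
        ],
    )
    return build_survey_table(df, roster)
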