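import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import twr

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_survey():
    """A 40-station synthetic survey plus its planted truth."""
    panel, truth = twr.generate_survey(twr.ScenarioConfig(n_stations=40, seed=7))
    return panel, truth


@pytest.fixture(scope="session")
def small_covariates(small_survey):
    """Standardized covariate table built from the 40-station survey."""
    panel, truth = small_survey
    panel = twr.substitute_below_limit(panel)
    panel, _ = twr.filter_stations(panel)
    table = twr.build_covariate_table(twr.log10_chemistry(panel))
    return panel, twr.standardize(table), truth


@pytest.fixture()
def toy_obs_csv(tmp_path):
    """Hand-written observation CSV: one station, pH in 2012 and 2018,
    plus one Ca row."""
    path = tmp_path / "obs.csv"
    path.write_text(
        "station_id,year,variable,value,below_limit,reporting_limit\n"
        "A,2012,pH,6.1,False,\n"
        "A,2018,pH,6.4,False,\n"
        "A,2012,Ca,3.2,False,\n"
    )
    return path


def make_panel(rows, attrs=None, climate=None):
    """Build a SurveyPanel from (station, year, variable, value[, below, limit])
    tuples."""
    recs = []
    for r in rows:
        sid, yr, var, val = r[:4]
        below = r[4] if len(r) > 4 else False
        limit = r[5] if len(r) > 5 else np.nan
        recs.append((sid, yr, var, val, below, limit))
    obs = pd.DataFrame(
        recs,
        columns=["station_id", "year", "variable", "value", "below_limit", "reporting_limit"],
    )
    return twr.SurveyPanel(observations=obs, attributes=attrs, climate=climate)
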