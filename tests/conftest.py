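import warnings

import pytest

from smokeqol import attribution, synthetic, windows
from smokeqol.geometry import default_study_area


@pytest.fixture(scope="session")
def study_area():
    return default_study_area()


@pytest.fixture(scope="session")
def small_config():
    """Compact 4-year study used by most pipeline tests."""
    return synthetic.SimulationConfig(
        seed=0, n_cells=4, n_subjects=250,
        date_range=("2009-01-01", "2012-12-31"),
    )


@pytest.fixture(scope="session")
def small_env(small_config):
    """Calendar, plumes, grid and ground truth for the compact study."""
    calendar, plumes = synthetic.gen_smoke_calendar(small_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid, truth = synthetic.gen_pollutant_fields(small_config, calendar)
    return {"calendar": calendar, "plumes": plumes, "grid": grid, "truth": truth}


@pytest.fixture(scope="session")
def small_daily(small_config, small_env):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regional = attribution.attribute_regional(small_env["grid"], small_env["calendar"])
    return windows.daily_exposure_table(regional, small_env["calendar"])


@pytest.fixture(scope="session")
def analysis_rows(small_config, small_env, small_daily):
    """Analysis-ready table: cohort + window metrics + outcome scores."""
    cohort = synthetic.gen_cohort(small_config)
    rows = windows.attach_exposures(cohort, small_daily)
    scores, truth = synthetic.gen_outcomes(cohort, rows, small_config)
    return rows.merge(scores, on="subject_id"), truth
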