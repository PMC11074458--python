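import numpy as np
import pytest

from templag.experiments import default_truth
from templag.pipeline import AnalysisConfig, prepare_design, _fit_subgroup
from templag.simulate import SimConfig, generate_series


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ten_year_series():
    """Ten-year synthetic series with the standard U-shaped truth surface."""
    cfg = SimConfig(random_seed=2026, truth_surface=default_truth("u-shaped"))
    frame, truth = generate_series(cfg)
    return frame, truth


@pytest.fixture(scope="session")
def two_year_series():
    cfg = SimConfig(random_seed=7, end_date="2012-12-31")
    frame, truth = generate_series(cfg)
    return frame, truth


@pytest.fixture(scope="session")
def total_fit(ten_year_series):
    """Prepared design and fitted total-deaths model on the ten-year series."""
    frame, truth = ten_year_series
    config = AnalysisConfig()
    prep = prepare_design(frame, config)
    fit = _fit_subgroup(prep, "total")
    return prep, fit, truth
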