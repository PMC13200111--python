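import datetime as dt

import numpy as np
import pytest

from protonqa.compare import ProjectionFactors
from protonqa.simulator import (
    CampaignSpec,
    ErrorModelConfig,
    default_error_model,
    make_fixture_plan,
)


@pytest.fixture(scope="session")
def small_plan():
    """A 3-layer, 12-spot-per-layer miniature of the QA fixture plan."""
    return make_fixture_plan(
        n_layers=3,
        spots_per_layer=12,
        energy_min=100.0,
        energy_max=120.0,
        total_mu=3.6,
        field_mm=60.0,
        plan_id="QA-SMALL",
    )


@pytest.fixture(scope="session")
def null_model():
    return ErrorModelConfig()


@pytest.fixture(scope="session")
def axis_model():
    """Error model with the campaign's observed per-axis distributions only."""
    return ErrorModelConfig(mu_x=0.163, sigma_x=0.199, mu_y=0.096, sigma_y=0.151)


def two_month_dates(n_first=3, n_second=2):
    first = [dt.date(2025, 5, d) for d in (5, 12, 19)][:n_first]
    second = [dt.date(2025, 6, d) for d in (9, 23)][:n_second]
    return first + second


@pytest.fixture()
def small_campaign(small_plan):
    """2 rooms x 5 paired dates over two months, mild systematic structure."""
    dates = two_month_dates()
    return CampaignSpec(
        rooms=["G1", "G2"],
        dates=dates,
        plan=small_plan,
        error_model=default_error_model(dates, seed=11),
        faults=[],
        factors=ProjectionFactors(),
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
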