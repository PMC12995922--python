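import pytest

from standres import fixtures as fx
from standres.config import RunConfig
from standres.disturbance import hazard_from_survival
from standres.growth_yield import interpolate_young_ages
from standres.pipeline import ParamSet


@pytest.fixture(scope="session")
def growth_table():
    """Synthetic yield table with young ages filled."""
    return interpolate_young_ages(fx.default_growth_table())


@pytest.fixture(scope="session")
def params(growth_table):
    """Full default parameter set of the shipped synthetic bundle."""
    return ParamSet(
        hazard=hazard_from_survival(fx.default_survival_model(), max_age=85),
        reduction=fx.default_hazard_reduction(),
        growth=growth_table,
        modifiers=fx.default_growth_modifiers(),
        valuation=fx.default_valuation_params(),
        carbon=fx.default_carbon_params(),
    )


@pytest.fixture()
def small_config():
    """Scaled-down study conditions for fast end-to-end checks."""
    return RunConfig(
        seed=7,
        n_runs=4,
        series_years=1500,
        horizon_years=1000,
        gap_sizes=[0.1, 0.3],
        gap_ages=[20, 60],
    )
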