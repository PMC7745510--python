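import hypothesis
import pandas as pd
import pytest

from hmisdq.journey import (
    DistrictSpec,
    JourneyParams,
    RosterConfig,
    SERVICE_AREAS,
    default_indicators,
    preset_lossless,
    propagate_journey,
    simulate_roster,
    simulate_true_events,
)

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


SMALL_ROSTER = RosterConfig(
    districts=(DistrictSpec("Alpha", "urban", 3), DistrictSpec("Beta", "rural", 3)),
    level_counts={"dispensary": 4, "health_centre": 1, "hospital": 1},
    ownership_counts={"government": 4, "faith_based": 1, "private": 1},
    offer_rates={sa: 1.0 for sa in SERVICE_AREAS},
)


@pytest.fixture(scope="session")
def small_roster():
    return simulate_roster(SMALL_ROSTER, seed=7)


@pytest.fixture(scope="session")
def indicators():
    return default_indicators()


@pytest.fixture(scope="session")
def lossless_params():
    return preset_lossless(seed=7)


@pytest.fixture(scope="session")
def lossless_counts(small_roster, indicators, lossless_params) -> pd.DataFrame:
    truth = simulate_true_events(
        small_roster, indicators, ("2015-01", "2015-12"), lossless_params
    )
    return propagate_journey(truth, lossless_params)


@pytest.fixture(scope="session")
def thinned_counts(small_roster, indicators) -> tuple[pd.DataFrame, JourneyParams]:
    """Journey with only register thinning (retention 0.8), reports from tallies."""
    params = JourneyParams(mean_monthly_volume=50.0, p_register_miss=0.2, seed=11)
    truth = simulate_true_events(small_roster, indicators, ("2014-01", "2015-12"), params)
    return propagate_journey(truth, params), params
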