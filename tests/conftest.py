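import pytest

import previnc as pv


@pytest.fixture(scope="session")
def default_scenario():
    return pv.make_default_scenario(seed=0)


@pytest.fixture(scope="session")
def default_truth(default_scenario):
    """Forward-solved prevalence on the integer-age grid at the wave years."""
    return pv.scenario_truth(default_scenario)


@pytest.fixture(scope="session")
def mortality(default_scenario):
    return pv.generate_mortality_schedule(default_scenario)


@pytest.fixture(scope="session")
def fitted_surface(default_scenario, default_truth):
    """Two-stage surface fitted to four moderate synthetic waves."""
    fits = []
    for k, year in enumerate(default_scenario.wave_years):
        rec = pv.generate_survey(
            default_scenario, year, n=20_000, seed=500 + k, truth=default_truth
        )
        fits.append(pv.fit_wave(rec))
    return pv.pool_waves(fits)
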