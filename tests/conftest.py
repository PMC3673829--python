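import pytest
from hypothesis import settings

from dmproj import run_projection, syria

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from dmproj.bands import AgeBand
from dmproj.synthetic import SyntheticCountrySpec, generate_country


@pytest.fixture(scope="session")
def syria_baseline():
    """The full 2003–2022 baseline projection on the published-inputs preset."""
    return run_projection(syria.projection_config())


@pytest.fixture(scope="session")
def syria_intervention():
    """The same projection under the 10-year prevention program."""
    return run_projection(syria.projection_config(scenario=syria.prevention_scenario()))


@pytest.fixture(scope="session")
def oracle_bundle():
    """Single open-band synthetic country with unit exposure RRs.

    With one age band there is no aging and with unit RRs every exposure
    compartment shares the population incidence, so the engine must match
    the two-compartment closed form exactly.
    """
    spec = SyntheticCountrySpec(
        bands=(AgeBand(25, None),),
        incidence=0.02,
        mortality_background=0.01,
        excess_mortality=0.008,
        dm_prev0=0.05,
        growth=0.0,
        rr_dm_obese=1.0,
        rr_dm_smoker=1.0,
    )
    return generate_country(spec)


@pytest.fixture(scope="session")
def curve_bundle():
    """Six-band bundle whose baseline prevalence curve is hazard-consistent."""
    spec = SyntheticCountrySpec(
        incidence=0.02,
        mortality_background=0.01,
        excess_mortality=0.005,
        baseline_from_hazards=True,
    )
    return generate_country(spec)
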