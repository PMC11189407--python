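import numpy as np
import pytest

from ssrlag import (
    assemble_model_frame,
    default_scenario,
    poznan_like_profile,
    simulate_birth_series,
    simulate_temperature,
)


@pytest.fixture(scope="session")
def profile():
    return poznan_like_profile()


@pytest.fixture(scope="session")
def temps(profile):
    return simulate_temperature(profile, seed=42)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=43)


@pytest.fixture(scope="session")
def births(temps, scenario):
    return simulate_birth_series(temps, scenario)


@pytest.fixture(scope="session")
def frame(births, temps):
    """Study-scale model frame (~618 months, 100 births/month)."""
    return assemble_model_frame(births, temps)


@pytest.fixture(scope="session")
def small_frame(profile):
    """A short, cheap frame for fits that only need structural checks."""
    prof = poznan_like_profile(start_year=1848, end_year=1858)
    t = simulate_temperature(prof, seed=7)
    sc = default_scenario(seed=8, births_per_month=50)
    b = simulate_birth_series(t, sc)
    return assemble_model_frame(b, t)


@pytest.fixture(scope="session")
def response(frame):
    return frame["girls"].to_numpy(float), frame["total"].to_numpy(float)
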