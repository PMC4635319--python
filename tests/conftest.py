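import pandas as pd
import pytest

from canopyn import (
    KineticConstants,
    NDistributionParams,
    PhotoParams25,
    StomatalParams,
    WeatherSpec,
    generate_weather_day,
)


@pytest.fixture(scope="session")
def kinetics() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def ndist() -> NDistributionParams:
    return NDistributionParams()


@pytest.fixture(scope="session")
def sp() -> StomatalParams:
    return StomatalParams()


@pytest.fixture(scope="session")
def p25() -> PhotoParams25:
    """A mid-canopy alfalfa-like leaf."""
    return PhotoParams25(vcmax25=90.0, jmax25=150.0, tpu25=10.0, rd25=1.2)


@pytest.fixture(scope="session")
def sunny_day() -> pd.DataFrame:
    """Clear 14-h day, half-sine peak 1100 umol/m2/s, 18-26 degC."""
    return generate_weather_day(WeatherSpec())


@pytest.fixture(scope="session")
def cloudy_day() -> pd.DataFrame:
    return generate_weather_day(WeatherSpec(day_type="cloudy", t_min=15.0, t_max=20.0))


@pytest.fixture()
def dark_day() -> pd.DataFrame:
    """24 h of darkness at constant 25 degC (reference-temperature checks)."""
    t = list(range(25))
    return pd.DataFrame(
        {
            "time_h": t,
            "ppfd_umol_m2_s": [0.0] * 25,
            "tair_c": [25.0] * 25,
            "vpd_kpa": [1.0] * 25,
            "ca_umol_mol": [400.0] * 25,
        }
    )
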