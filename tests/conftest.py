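import numpy as np
import pytest

import wheatclim as wc
from wheatclim.config import demo_dry_site, demo_wet_site


@pytest.fixture(scope="session")
def dry_site() -> wc.SiteClimate:
    return demo_dry_site()


@pytest.fixture(scope="session")
def wet_site() -> wc.SiteClimate:
    return demo_wet_site()


@pytest.fixture(scope="session")
def cultivar() -> wc.CultivarParams:
    return wc.CultivarParams()


@pytest.fixture(scope="session")
def soil() -> wc.SoilProfile:
    return wc.SoilProfile()


@pytest.fixture(scope="session")
def dry_weather(dry_site) -> list[wc.WeatherSeries]:
    """Ten baseline seasons at the dry demo site, shared across tests."""
    return wc.generate_weather(dry_site, 10, seed=101)


@pytest.fixture(scope="session")
def wet_weather(wet_site) -> list[wc.WeatherSeries]:
    return wc.generate_weather(wet_site, 10, seed=202)
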