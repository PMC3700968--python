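import numpy as np
import pytest

import frosthatch as fh


@pytest.fixture(scope="session")
def cold_site():
    return fh.SITE_PRESETS["north-plains"]


@pytest.fixture(scope="session")
def short_daily(cold_site):
    """Three years of cold-continental daily weather, fixed seed."""
    return fh.generate_daily_series(cold_site, 3, seed=11)


@pytest.fixture(scope="session")
def bare_run_3y():
    """A 3-year bare-soil run on the cold site (shared across tests)."""
    cfg = fh.make_scenario("MAIZE+TILL", "north-plains", n_years=3, seed=11)
    return cfg, fh.run_scenario(cfg)
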