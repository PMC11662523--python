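import numpy as np
import pandas as pd
import pytest

import heatmort as hm


@pytest.fixture(scope="session")
def small_config():
    """A light panel: 3 municipalities over 6 seasons, strong heat effect."""
    return hm.SynthConfig(n_units=3, year_start=2000, year_end=2005,
                          baseline_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return hm.generate_panel(small_config)


@pytest.fixture(scope="session")
def small_model(small_panel):
    return hm.fit_heat_model(small_panel)


@pytest.fixture()
def toy_spec():
    """Tiny cross-basis spec with closed-form pieces: linear exposure basis
    (no internal knots), lag window 0-2 with a linear-plus-intercept lag
    basis."""
    return hm.KnotSpec(var_knots=(), var_boundary=(0.0, 10.0),
                       lag_max=2, lag_knots=())


def make_panel(units, dates, tmean, deaths, **extra):
    """Assemble a panel frame from aligned arrays."""
    df = pd.DataFrame({"unit": units, "date": pd.to_datetime(dates),
                       "tmean": tmean, "deaths": deaths})
    for k, v in extra.items():
        df[k] = v
    return df
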