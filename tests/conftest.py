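import numpy as np
import pandas as pd
import pytest

import migsim as m


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world: 12 countries, 1990-2010."""
    cfg = m.SyntheticConfig(n_countries=12, seed=11, end_year=2010)
    panel, initial = m.generate_world(cfg)
    return cfg, panel, initial


@pytest.fixture(scope="session")
def truth():
    return m.default_truth()


@pytest.fixture(scope="session")
def synthetic_history():
    """Closed-loop inputs at the standard study scale (40 countries)."""
    cfg = m.SyntheticConfig(n_countries=40, seed=1)
    panel, initial = m.generate_world(cfg)
    truth = m.default_truth()
    return cfg, truth, m.generate_flow_history(panel, initial, truth, seed=101)


@pytest.fixture(scope="session")
def calibrated(synthetic_history):
    cfg, truth, res = synthetic_history
    dists = m.calibrate_model(res.history, res.stocks, res.panel,
                              scheme=cfg.scheme)
    return cfg, truth, res, dists


def make_panel(countries, years, population, natural_change=0.0,
               birth_rate=0.0, death_rate=0.0, gdpc=1e4):
    """Tiny hand-built panel; scalar arguments broadcast over countries."""
    def vec(x):
        return np.broadcast_to(np.asarray(x, dtype=float), (len(countries),))

    rows = []
    for y in years:
        for c, p, nc, cb, cd, g in zip(
            countries, vec(population), vec(natural_change),
            vec(birth_rate), vec(death_rate), vec(gdpc)
        ):
            rows.append((c, y, p, nc, cb, cd, g, "R1", "high"))
    return m.CountryPanel(pd.DataFrame(rows, columns=[
        "country_id", "year", "population", "natural_change_rate",
        "birth_rate", "death_rate", "gdpc", "region", "income_group",
    ]))
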