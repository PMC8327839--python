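import numpy as np
import pandas as pd
import pytest

from healthexp import synth
from healthexp.taxonomy import Layout, default_hc_tree, default_hp_tree


@pytest.fixture(scope="session")
def hc_tree():
    return default_hc_tree()


@pytest.fixture(scope="session")
def hp_tree():
    return default_hp_tree()


@pytest.fixture(scope="session")
def layout(hc_tree, hp_tree):
    return Layout(hc_tree, hp_tree)


@pytest.fixture(scope="session")
def small_world():
    """A 6-country world shared by read-only tests."""
    return synth.generate_world(synth.WorldConfig(n_countries=6, seed=11))


@pytest.fixture(scope="session")
def noise_free_world():
    """Distortion-free world: every reporting artefact switched off."""
    cfg = synth.noise_free(
        synth.WorldConfig(n_countries=5, seed=13, never_report_frac=0.0)
    )
    return synth.generate_world(cfg)


def make_obs(rows):
    """Observation table from (country, year, hc, hp, amount, currency,
    vintage, sha, capital) tuples, with sensible defaults."""
    full = []
    for r in rows:
        d = {
            "country": "AAA", "year": 2010, "hc_code": "HC1", "hp_code": None,
            "amount": 1.0, "currency": "USD2017", "report_vintage": 2012,
            "sha_version": 2011, "is_capital_formation": False,
        }
        d.update(r)
        full.append(d)
    from healthexp.harmonize import OBS_COLUMNS

    return pd.DataFrame(full, columns=OBS_COLUMNS)


@pytest.fixture
def obs_factory():
    return make_obs
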