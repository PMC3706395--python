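import numpy as np
import pandas as pd
import pytest

from grassrisk.species_table import Dataset
from grassrisk.synthetic_data import default_fixture


def make_dataset(
    genus,
    high_impact,
    spread_rate_regions=None,
    naturalisation_year=1959,
    semi_aquatic=None,
    census_year=2009,
    **overrides,
):
    """Hand-rolled small Dataset: one row per entry of ``genus``.

    ``spread_rate_regions`` sets num_regions directly (with the default year,
    spread_rate = num_regions / 5 decades).
    """
    n = len(genus)
    high_impact = list(high_impact)
    base = {
        "species_id": [f"sp{i}" for i in range(n)],
        "genus": list(genus),
        "num_regions": spread_rate_regions or [5] * n,
        "naturalisation_year": [naturalisation_year] * n,
        "actively_spread": [0] * n,
        "intro_pathway": ["crop"] * n,
        "semi_aquatic": semi_aquatic or [0] * n,
        "life_history": ["annual"] * n,
        "tufted": ["no"] * n,
        "rhizomes": ["no"] * n,
        "stolons": ["no"] * n,
        "incidence": [10] * n,
        "high_impact": high_impact,
        "impact_env": high_impact,
        "impact_pastoral": [0] * n,
        "impact_agri": [0] * n,
    }
    base.update(overrides)
    return Dataset(pd.DataFrame(base), census_year=census_year)


def random_grouped_dataset(rng, n_genera=4, max_size=7, beta=(-1.0, 0.6), sigma=0.7):
    """Random small dataset from the genus-intercept logistic model itself."""
    from scipy.special import expit

    genus, regions, years, y = [], [], [], []
    u = rng.normal(0.0, sigma, n_genera)
    for j in range(n_genera):
        for _ in range(int(rng.integers(2, max_size + 1))):
            genus.append(f"g{j}")
            nr = int(rng.integers(1, 40))
            yr = int(rng.integers(1880, 1995))
            regions.append(nr)
            years.append(yr)
            spread = nr / ((2009 - yr) / 10)
            y.append(int(rng.random() < expit(beta[0] + beta[1] * spread + u[j])))
    df = pd.DataFrame(
        {
            "species_id": [f"sp{i}" for i in range(len(genus))],
            "genus": genus,
            "num_regions": regions,
            "naturalisation_year": years,
            "actively_spread": 0,
            "intro_pathway": "crop",
            "semi_aquatic": 0,
            "life_history": "annual",
            "tufted": "no",
            "rhizomes": "no",
            "stolons": "no",
            "incidence": 10,
            "high_impact": y,
            "impact_env": y,
            "impact_pastoral": 0,
            "impact_agri": 0,
        }
    )
    return Dataset(df)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The deterministic 155-species study-structure dataset."""
    return default_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20090101)
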