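import numpy as np
import pandas as pd
import pytest

from aflpop import MarkerMatrix, SyntheticConfig, simulate_population


def make_matrix(values, ids=None, loci=None) -> MarkerMatrix:
    values = np.asarray(values)
    n, L = values.shape
    return MarkerMatrix(
        ids or [f"i{k}" for k in range(n)],
        loci or [f"l{k}" for k in range(L)],
        values,
    )


def make_meta(ids, webs, ages=None, sexes=None, positions=None) -> pd.DataFrame:
    n = len(ids)
    webs = list(webs)
    if positions is None:
        web_pos = {w: 100.0 * i for i, w in enumerate(dict.fromkeys(webs))}
        positions = [web_pos[w] for w in webs]
    return pd.DataFrame(
        {
            "individual_id": ids,
            "web_id": webs,
            "age_class": ages or ["adult"] * n,
            "sex": sexes or ["female"] * n,
            "easting": positions,
            "northing": 0.0,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sib_dataset():
    """Strongly kin-structured survey: every web one full-sib family."""
    cfg = SyntheticConfig(
        seed=42, n_webs=10, group_size_min=6, group_size_max=6,
        n_loci=100, sib_fraction=1.0, migrant_rate=0.0,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def panmictic_dataset():
    """No structure at all: every individual an independent global draw."""
    cfg = SyntheticConfig(
        seed=43, n_webs=10, group_size_min=5, group_size_max=5,
        n_loci=150, sib_fraction=0.0, migrant_rate=1.0,
    )
    return simulate_population(cfg)
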