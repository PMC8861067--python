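import numpy as np
import pandas as pd
import pytest

import stopover as st


def make_tm(n_islands=4, years=3, n_species=5, seed=0):
    """Random unbalanced community matrix, chord-transformed."""
    rng = np.random.default_rng(seed)
    if np.isscalar(years):
        years = [years] * n_islands
    rows, index = [], []
    for i in range(n_islands):
        for k in range(years[i]):
            rows.append(rng.integers(1, 50, size=n_species))
            index.append((f"I{i+1}", 2000 + k))
    counts = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["island", "year"]),
        columns=[f"SP{j+1}" for j in range(n_species)])
    return st.chord_transform(st.CommunityMatrix(counts))


@pytest.fixture(scope="session")
def island_table():
    return st.load_island_table()


@pytest.fixture(scope="session")
def synthetic_world():
    """Default-condition synthetic dataset shared across tests."""
    cfg = st.SyntheticConfig(seed=11)
    captures, effort, truth = st.simulate_ringing(cfg)
    return cfg, captures, effort, truth


@pytest.fixture(scope="session")
def synthetic_tm(synthetic_world):
    _, captures, _, _ = synthetic_world
    filtered, _ = st.filter_species(captures)
    return st.chord_transform(st.pivot(filtered))
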