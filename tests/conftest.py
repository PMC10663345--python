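import numpy as np
import pandas as pd
import pytest

import endostat as es


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """3 samples x 2 ASVs with hand-readable counts."""
    counts = pd.DataFrame(
        [[5.0, 0.0], [1.0, 2.0], [0.0, 7.0]],
        index=["s1", "s2", "s3"], columns=["a1", "a2"],
    )
    return es.AsvTable(counts)


@pytest.fixture
def valid_metadata_frame():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "soil1"],
        "plant_id": ["p1", "p1", "p2", pd.NA],
        "genotype": ["lore", "lore", "WT", pd.NA],
        "tissue": ["root", "rosette", "root", "soil"],
        "stage": ["Vegetative", "Vegetative", "Flowering", pd.NA],
        "run": ["runA"] * 4,
        "plate": ["plate1"] * 4,
        "amplicon": ["16S"] * 4,
    })


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated Vegetative-stage dataset shared across tests."""
    cfg = es.SimConfig(seed=42, stages=["Vegetative"],
                       n_plants_per_genotype_per_stage=4, n_soil_samples=4,
                       n_asvs=60)
    table, meta, registry, tree = es.simulate_dataset(cfg)
    return cfg, table, meta, registry, tree


def random_count_table(rng, n_samples=12, n_asvs=20, depth_low=50,
                       depth_high=4000):
    """Random integer table with heavy-tailed depth variation."""
    depths = rng.integers(depth_low, depth_high, n_samples)
    p = rng.dirichlet(np.full(n_asvs, 0.4))
    mat = np.stack([rng.multinomial(d, p) for d in depths]).astype(float)
    ids = [f"s{i}" for i in range(n_samples)]
    cols = [f"a{j}" for j in range(n_asvs)]
    return es.AsvTable(pd.DataFrame(mat, index=ids, columns=cols))
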