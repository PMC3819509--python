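import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from fatscan import (GenotypeMatrix, MarkerMap, RunConfig, SimConfig,
                     TraitTable, simulate_genotypes, simulate_trait)


@pytest.fixture(scope="session")
def toy_genotypes():
    """3 animals x 2 SNPs with known dosages."""
    return GenotypeMatrix(["a1", "a2", "a3"], ["s1", "s2"],
                          np.array([[0., 2.], [1., 1.], [2., 0.]]))


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with one strong QTL window (seed-fixed)."""
    cfg = SimConfig(n_animals=300, n_snps=400, h2_target=0.5, seed=7,
                    qtl_spec=[("2_0", 2, 0.7), ("5_0", 1, 0.3)])
    genos, mmap = simulate_genotypes(cfg)
    traits, truth = simulate_trait(genos, mmap, cfg)
    return cfg, genos, mmap, traits, truth


@pytest.fixture()
def short_cfg():
    """Short but well-formed chain settings for cheap tests."""
    return RunConfig(n_iter=2000, n_burn=500, thin=5, seed=11)


@pytest.fixture(scope="session")
def trait_table():
    rng = np.random.default_rng(3)
    n = 30
    df = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(n)],
        "contemporary_group": [f"g{i % 3}" for i in range(n)],
        "fat_thickness": rng.normal(size=n),
        "lma": rng.normal(size=n),
        "hcw": rng.normal(size=n),
        "extracted_fat": rng.normal(size=n),
        "trait": rng.normal(size=n),
    })
    return TraitTable(df)
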