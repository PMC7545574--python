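import warnings

import numpy as np
import pandas as pd
import pytest

from micromr.simulate import (SimulationConfig, simulate_genotypes,
                              simulate_taxon_table)

warnings.filterwarnings("ignore", message=".*monomorphic.*")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale cohort configuration shared by the slower tests."""
    return SimulationConfig(n_samples=600, n_variants=600, n_taxa_common=25,
                            n_taxa_rare=10, taxon_h2=0.4, n_causal_per_taxon=10,
                            seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    G = simulate_genotypes(small_config)
    table, truth = simulate_taxon_table(G, small_config)
    return G, table, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def toy_summary_stats(**overrides) -> pd.DataFrame:
    """One-variant template summary-statistics row, overridable per column."""
    base = {
        "variant_id": "rs1", "chrom": "1", "pos_bp": 100, "pos_cm": 1e-4,
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
        "beta": 0.1, "se": 0.02, "p": 1e-6, "n": 1000,
    }
    base.update(overrides)
    return pd.DataFrame([base])
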