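import numpy as np
import pytest

from ricedus import (
    SimulationConfig,
    encode_phenotypes,
    impute_mode,
    simulate_genotypes,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_panel():
    """A small imputed genotype panel with traits, shared across tests."""
    cfg = SimulationConfig(
        n_varieties=30,
        n_loci=200,
        n_subpops=3,
        fst=0.2,
        n_traits=6,
        h2=[0.9, 0.8, 0.6, 0.4, 0.2, 0.0],
        n_causal=40,
        n_levels=5,
        missing_rate=0.05,
        seed=42,
    )
    g, subpop = simulate_genotypes(cfg)
    gi = impute_mode(g)
    traits, truth = simulate_traits(gi, cfg)
    return {
        "config": cfg,
        "raw": g,
        "genotypes": gi,
        "subpop": subpop,
        "traits": traits,
        "truth": truth,
        "pheno": encode_phenotypes(traits),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
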