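import numpy as np
import pandas as pd
import pytest

from metabosysgen.synthetic import (
    QtlEffect,
    SimulationConfig,
    TraitSpec,
    simulate_genotypes,
    simulate_panel,
)


def common_variants(genotypes: pd.DataFrame, min_minor: int = 15) -> list[int]:
    """Column indices of variants with a near-balanced minor class, where
    rank-correlation-based stages have power."""
    counts = genotypes.sum(axis=0).to_numpy()
    n = genotypes.shape[0]
    minor = np.minimum(counts, n - counts)
    return [int(i) for i in np.where(minor >= min_minor)[0]]


def chain_config(seed: int, n_variants: int = 60, n_metabolites: int = 12,
                 n_genes: int = 6, effect: float = 2.5) -> SimulationConfig:
    """Panel with one planted variant -> (gene, metabolite) -> trait chain on a
    common variant."""
    base = SimulationConfig(n_lines=40, n_variants=n_variants,
                            n_metabolites=n_metabolites, n_genes=n_genes, seed=seed)
    g = simulate_genotypes(base)
    v = common_variants(g)[0]
    return SimulationConfig(
        n_lines=40, n_variants=n_variants, n_metabolites=n_metabolites,
        n_genes=n_genes, seed=seed,
        mqtl_spec=(QtlEffect(v, 0, effect),),
        eqtl_spec=(QtlEffect(v, 0, effect),),
        trait_spec=(TraitSpec((0,), (1.0,), 0.7, name="focal"),),
    )


@pytest.fixture(scope="session")
def small_panel():
    """40-line panel with module structure, a planted mQTL and a sparse trait."""
    cfg = SimulationConfig(
        n_lines=40, n_variants=300, n_metabolites=40, n_genes=8, seed=42,
        module_spec=((10, 0.7), (8, 0.6)),
        mqtl_spec=(QtlEffect(5, 0, 2.0),),
        trait_spec=(TraitSpec((0, 1, 2), (1.0, 0.8, -0.5), 0.6, name="starvation"),),
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
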