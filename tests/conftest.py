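import numpy as np
import pandas as pd
import pytest

from lactgwas.kinship import GenotypeSet
from lactgwas.simulate import (
    SimulationConfig,
    drop_genotypes,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_founders=60, n_generations=2, n_animals_target=300,
        n_snp=300, n_chromosomes=3, chromosome_length_bp=500_000,
        n_qtl=3, seed=42,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    """Pedigree + genotypes for all animals (session-scoped, deterministic)."""
    rng = small_config.rng()
    pedigree = simulate_pedigree(small_config, rng)
    genotypes = drop_genotypes(pedigree, small_config, rng)
    return pedigree, genotypes


def random_genotypes(rng, n_animals, n_snp, chrom=1, maf_low=0.1, maf_high=0.5):
    """Independent (no-LD) genotype panel for null/oracle tests."""
    p = rng.uniform(maf_low, maf_high, n_snp)
    dos = rng.binomial(2, p, size=(n_animals, n_snp)).astype(float)
    mm = pd.DataFrame({
        "snp": [f"s{i}" for i in range(n_snp)],
        "chrom": chrom,
        "bp": np.arange(1, n_snp + 1) * 1000,
    })
    return GenotypeSet(dosages=dos, marker_map=mm,
                       animal_ids=np.arange(1, n_animals + 1))
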