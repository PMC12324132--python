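import numpy as np
import pytest

import popstruct as ps


@pytest.fixture(scope="session")
def small_dataset():
    """2 superpops x 2 subpops x 30 samples, 6 loci (one triallelic)."""
    cfg = ps.SimulationConfig(
        n_superpops=2,
        subpops_per_superpop=2,
        samples_per_subpop=30,
        n_loci=6,
        seed=11,
        triallelic_loci=(2,),
        fst_between_superpops=0.08,
        fst_within_superpop=0.02,
    )
    return ps.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_missing():
    """Same structure with 10% missing calls."""
    cfg = ps.SimulationConfig(
        n_superpops=2,
        subpops_per_superpop=2,
        samples_per_subpop=30,
        n_loci=6,
        seed=12,
        triallelic_loci=(2,),
        missing_rate=0.1,
    )
    return ps.simulate_dataset(cfg)


def random_genotype_matrix(rng, n_pops=3, n_ind=10, n_loci=2, max_alleles=3, missing_rate=0.05):
    """Small random multiallelic matrix plus a population label list."""
    samples = [f"S{i}" for i in range(n_pops * n_ind)]
    labels = [f"P{p}" for p in range(n_pops) for _ in range(n_ind)]
    loci = [f"rs{l}" for l in range(n_loci)]
    alleles = []
    codes = np.empty((len(samples), n_loci, 2), dtype=np.int8)
    for l in range(n_loci):
        k = int(rng.integers(2, max_alleles + 1))
        alleles.append(tuple("ACGT"[:k]))
        codes[:, l, :] = rng.integers(0, k, size=(len(samples), 2))
    miss = rng.random((len(samples), n_loci)) < missing_rate
    codes[miss] = -1
    gm = ps.GenotypeMatrix(samples, loci, alleles, codes)
    return gm, labels
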