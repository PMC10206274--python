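import numpy as np
import pytest

from layersim.founders import Demography, GenomeMap, partition_loci, simulate_founders
from layersim.inheritance import FEMALE, MALE, PedigreeTable


@pytest.fixture(scope="session")
def tiny_pop():
    """Small founder population: 1 chromosome, 1 Mb, 40 animals, 60 sites."""
    gm = GenomeMap.reduced(n_chromosomes=1, physical_length_per_chr=1.0e6)
    return simulate_founders(gm, Demography(), n_individuals=40, sites_per_chr=60, seed=101)


@pytest.fixture(scope="session")
def tiny_partition(tiny_pop):
    return partition_loci(tiny_pop, (10, 25, 25), seed=11)


def random_pedigree(n_founders: int, n_per_gen: int, n_gens: int, seed: int) -> PedigreeTable:
    """Random multi-generation pedigree (shared across kinship oracles)."""
    rng = np.random.default_rng(seed)
    ped = PedigreeTable()
    sexes = np.where(np.arange(n_founders) % 2 == 0, MALE, FEMALE).astype(np.int8)
    ped.add(np.zeros(n_founders, np.int64), np.zeros(n_founders, np.int64), sexes, 0.0)
    for g in range(1, n_gens + 1):
        ids = ped.animal_id
        males = ids[ped.sex == MALE]
        females = ids[ped.sex == FEMALE]
        s = rng.choice(males, n_per_gen)
        d = rng.choice(females, n_per_gen)
        sx = np.where(rng.random(n_per_gen) < 0.5, MALE, FEMALE).astype(np.int8)
        ped.add(s, d, sx, float(g))
    return ped


def kinship_oracle(ped: PedigreeTable):
    """Independent recursive kinship oracle (memoized path counting)."""
    import functools

    sire = ped.sire_id
    dam = ped.dam_id

    @functools.lru_cache(maxsize=None)
    def a(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        if i == j:
            return 1.0 + 0.5 * a(int(sire[i - 1]), int(dam[i - 1]))
        if j > i:
            i, j = j, i
        return 0.5 * (a(int(sire[i - 1]), j) + a(int(dam[i - 1]), j))

    n = ped.n
    return np.array([[a(i, j) for j in range(1, n + 1)] for i in range(1, n + 1)])
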