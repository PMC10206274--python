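"""Meiosis, offspring generation, and pedigree bookkeeping.

Crossovers follow a Poisson process on the genetic map (no interference, no
obligate chiasma) and there is no mutation after the base population.  The
hot loop is a numba kernel operating on whole batches of gametes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .founders import GenomeMap, HaplotypePopulation

__all__ = ["PedigreeTable", "meiosis", "make_offspring", "drop_gametes"]

MALE, FEMALE = 1, 2


@dataclass
class PedigreeTable:
    """Animal / sire / dam / sex / birth-time records.

    Animal ids are 1-based and dense (id == row + 1); 0 denotes an unknown
    parent.  Parents always precede offspring.
    """

    animal_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    sire_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    dam_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    sex: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    birth_time: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    @property
    def n(self) -> int:
        return self.animal_id.size

    def add(self, sire_id, dam_id, sex, birth_time) -> np.ndarray:
        """Append a batch of animals; returns their new ids."""
        sire_id = np.asarray(sire_id, dtype=np.int64)
        dam_id = np.asarray(dam_id, dtype=np.int64)
        k = sire_id.size
        new_ids = np.arange(self.n + 1, self.n + k + 1, dtype=np.int64)
        if k == 0:
            return new_ids
        if np.any(sire_id >= new_ids[0]) or np.any(dam_id >= new_ids[0]):
            raise ValueError("unknown parent id (parents must precede offspring)")
        m = sire_id > 0
        if np.any(self.sex[sire_id[m] - 1] != MALE):
            raise ValueError("sire is not male")
        m = dam_id > 0
        if np.any(self.sex[dam_id[m] - 1] != FEMALE):
            raise ValueError("dam is not female")
        self.animal_id = np.concatenate([self.animal_id, new_ids])
        self.sire_id = np.concatenate([self.sire_id, sire_id])
        self.dam_id = np.concatenate([self.dam_id, dam_id])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.birth_time = np.concatenate(
            [self.birth_time, np.full(k, float(birth_time)) if np.isscalar(birth_time) else np.asarray(birth_time, dtype=float)]
        )
        return new_ids

    def rows(self, ids) -> np.ndarray:
        return np.asarray(ids, dtype=np.int64) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "sire_id": self.sire_id,
                "dam_id": self.dam_id,
                "sex": np.where(self.sex == MALE, "M", "F"),
                "birth_time": self.birth_time,
            }
        )

    def write_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str) -> "PedigreeTable":
        df = pd.read_csv(path)
        return cls(
            animal_id=df["animal_id"].to_numpy(np.int64),
            sire_id=df["sire_id"].to_numpy(np.int64),
            dam_id=df["dam_id"].to_numpy(np.int64),
            sex=np.where(df["sex"].to_numpy() == "M", MALE, FEMALE).astype(np.int8),
            birth_time=df["birth_time"].to_numpy(float),
        )


@njit(cache=True)
def _gamete_kernel(haps, parent_rows, gpos, n_x, x_flat, x_offsets, phase, out):
    """Fill ``out`` with one gamete per meiosis.

    haps: (2n, L) parental haplotypes; parent_rows: animal row (not haplotype
    row) per meiosis; gpos: locus genetic positions (sorted, Morgans);
    x_flat/x_offsets: sorted crossover positions per meiosis (CSR layout);
    phase: starting haplotype (0/1) per meiosis.
    """
    n_loci = gpos.size
    for i in range(parent_rows.size):
        base = 2 * parent_rows[i]
        cur = phase[i]
        lo = x_offsets[i]
        hi = x_offsets[i] + n_x[i]
        j = lo
        for l in range(n_loci):
            while j < hi and x_flat[j] <= gpos[l]:
                cur = 1 - cur
                j += 1
            out[i, l] = haps[base + cur, l]


def drop_gametes(
    haps: np.ndarray,
    parent_rows: np.ndarray,
    gpos: np.ndarray,
    genetic_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one recombinant gamete per entry of ``parent_rows``.

    Crossover counts are Poisson(genetic_length); positions uniform on the
    genetic map.  Returns a (len(parent_rows), n_loci) uint8 array.
    """
    parent_rows = np.asarray(parent_rows, dtype=np.int64)
    m = parent_rows.size
    n_x = rng.poisson(genetic_length, size=m)
    total = int(n_x.sum())
    x_flat = rng.random(total) * genetic_length
    x_offsets = np.zeros(m, dtype=np.int64)
    if m > 1:
        np.cumsum(n_x[:-1], out=x_offsets[1:])
    # sort crossover positions within each meiosis
    if total:
        owner = np.repeat(np.arange(m), n_x)
        x_flat = x_flat[np.lexsort((x_flat, owner))]
    phase = rng.integers(0, 2, size=m).astype(np.int64)
    out = np.empty((m, gpos.size), dtype=np.uint8)
    _gamete_kernel(
        np.ascontiguousarray(haps),
        parent_rows,
        np.ascontiguousarray(gpos, dtype=np.float64),
        n_x.astype(np.int64),
        x_flat,
        x_offsets,
        phase,
        out,
    )
    return out


def meiosis(parent_haplotypes: list, genome: GenomeMap, seed: int) -> list:
    """One gamete from a single parent; ``parent_haplotypes[c]`` is (2, L).

    Returns one haplotype array per chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gamete = []
    for c, h in enumerate(parent_haplotypes):
        gpos = genome.genetic_positions(c)
        gamete.append(drop_gametes(h, np.zeros(1, np.int64), gpos, genome.genetic_length_per_chr, rng)[0])
    return gamete


def make_offspring(
    pop: HaplotypePopulation,
    ped: PedigreeTable,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    sexes: np.ndarray,
    birth_time: float,
    rng: np.random.Generator,
) -> HaplotypePopulation:
    """Create offspring from per-offspring parent rows (rows into ``pop``).

    ``sire_rows[i]`` / ``dam_rows[i]`` index animals in ``pop``; the pedigree
    is extended with the corresponding (global) ids, and a new
    HaplotypePopulation of the offspring cohort is returned.
    """
    sire_rows = np.asarray(sire_rows, dtype=np.int64)
    dam_rows = np.asarray(dam_rows, dtype=np.int64)
    genome = pop.genome
    haps = []
    for c, h in enumerate(pop.haplotypes):
        gpos = genome.genetic_positions(c)
        pat = drop_gametes(h, sire_rows, gpos, genome.genetic_length_per_chr, rng)
        mat = drop_gametes(h, dam_rows, gpos, genome.genetic_length_per_chr, rng)
        out = np.empty((2 * sire_rows.size, h.shape[1]), dtype=np.uint8)
        out[0::2] = pat
        out[1::2] = mat
        haps.append(out)
    ids = ped.add(
        sire_id=pop.animal_ids[sire_rows],
        dam_id=pop.animal_ids[dam_rows],
        sex=sexes,
        birth_time=birth_time,
    )
    return HaplotypePopulation(haplotypes=haps, animal_ids=ids, genome=genome)
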