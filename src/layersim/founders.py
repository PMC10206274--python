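"""Base-population genomes: coalescent founder haplotypes and locus partitioning.

Founder haplotypes are generated with the msprime coalescent engine under a
piecewise-constant effective-size history (optionally refined by log-linear
interpolation between the configured anchor epochs).  Mutation acts only
inside this founder simulation; all later steps are pure gene dropping.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import msprime
import numpy as np

__all__ = [
    "GenomeMap",
    "Demography",
    "LociPartition",
    "HaplotypePopulation",
    "simulate_founders",
    "partition_loci",
    "save_population",
    "load_population",
]

#: anchor epochs (generations ago, effective size) for the default history:
#: a small recent population expanding back to a very large ancestral one.
DEFAULT_EPOCHS = ((0.0, 100.0), (1.0e4, 1.0e3), (1.0e5, 1.0e4), (1.0e6, 5.0e5))


@dataclass(frozen=True)
class GenomeMap:
    """Genome layout: equally sized chromosomes with uniform recombination.

    Genetic position of a locus is its physical position times
    ``recombination_rate`` (Morgans).
    """

    n_chromosomes: int = 39
    physical_length_per_chr: float = 1.2e9 / 39
    recombination_rate: float = 2.5e-8
    mutation_rate: float = 5.0e-8
    #: locus physical positions per chromosome; filled by simulate_founders
    positions: tuple | None = None

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.physical_length_per_chr <= 0 or self.recombination_rate < 0:
            raise ValueError("invalid genome dimensions")
        if self.positions is not None:
            if len(self.positions) != self.n_chromosomes:
                raise ValueError("positions must cover every chromosome")
            for c, pos in enumerate(self.positions):
                pos = np.asarray(pos)
                if pos.size and not np.all(np.diff(pos) > 0):
                    raise ValueError(f"positions not strictly increasing on chromosome {c}")
                if pos.size and (pos[0] < 0 or pos[-1] >= self.physical_length_per_chr):
                    raise ValueError(f"positions out of range on chromosome {c}")

    @property
    def genetic_length_per_chr(self) -> float:
        """Genetic length of one chromosome in Morgans."""
        return self.physical_length_per_chr * self.recombination_rate

    @property
    def total_genetic_length(self) -> float:
        return self.n_chromosomes * self.genetic_length_per_chr

    def with_positions(self, positions) -> "GenomeMap":
        return replace(self, positions=tuple(np.asarray(p, dtype=np.int64) for p in positions))

    def genetic_positions(self, chrom: int) -> np.ndarray:
        """Locus genetic positions (Morgans) on one chromosome."""
        if self.positions is None:
            raise ValueError("no locus positions set")
        return np.asarray(self.positions[chrom], dtype=float) * self.recombination_rate

    @classmethod
    def full_scale(cls) -> "GenomeMap":
        """39 chromosomes, 30 Morgans / 1.2 Gb total."""
        return cls()

    @classmethod
    def reduced(cls, n_chromosomes: int = 5, physical_length_per_chr: float = 2.0e6) -> "GenomeMap":
        return cls(n_chromosomes=n_chromosomes, physical_length_per_chr=physical_length_per_chr)


@dataclass(frozen=True)
class Demography:
    """Piecewise effective-size history, most recent epoch first."""

    epochs: tuple = DEFAULT_EPOCHS
    interpolation_rule: str = "piecewise-constant"
    #: extra log-linear interpolation steps inserted between anchor epochs
    refine_steps: int = 0

    def __post_init__(self):
        times = [t for t, _ in self.epochs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("epoch times must be non-decreasing")
        if any(n <= 0 for _, n in self.epochs):
            raise ValueError("effective sizes must be positive")

    def schedule(self):
        """Expanded (time, size) schedule including interpolated steps."""
        pts = [(float(t), float(n)) for t, n in self.epochs]
        if self.refine_steps <= 0:
            return pts
        out = [pts[0]]
        for (t0, n0), (t1, n1) in zip(pts, pts[1:]):
            if t1 <= max(t0, 1.0):
                out.append((t1, n1))
                continue
            lo = max(t0, 1.0)
            ts = np.exp(np.linspace(np.log(lo), np.log(t1), self.refine_steps + 2))[1:]
            ns = np.exp(np.interp(np.log(ts), [np.log(lo), np.log(t1)], [np.log(n0), np.log(n1)]))
            out.extend(zip(ts.tolist(), ns.tolist()))
        return out

    def to_msprime(self) -> msprime.Demography:
        sched = self.schedule()
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=sched[0][1])
        for t, n in sched[1:]:
            dem.add_population_parameters_change(time=t, initial_size=n, population="pop")
        return dem

    @classmethod
    def constant(cls, ne: float) -> "Demography":
        return cls(epochs=((0.0, float(ne)),), interpolation_rule="constant")


@dataclass(frozen=True)
class LociPartition:
    """Disjoint QTL / SNP / neutral index sets per chromosome."""

    qtl_idx: tuple
    snp_idx: tuple
    neutral_idx: tuple

    def __post_init__(self):
        for c, (q, s, n) in enumerate(zip(self.qtl_idx, self.snp_idx, self.neutral_idx)):
            sets = [set(np.asarray(q).tolist()), set(np.asarray(s).tolist()), set(np.asarray(n).tolist())]
            if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
                raise ValueError(f"overlapping loci classes on chromosome {c}")

    @property
    def n_chromosomes(self) -> int:
        return len(self.qtl_idx)

    def counts(self):
        return (
            sum(len(q) for q in self.qtl_idx),
            sum(len(s) for s in self.snp_idx),
            sum(len(n) for n in self.neutral_idx),
        )

    def by_class(self, loci_class: str) -> tuple:
        return {"qtl": self.qtl_idx, "snp": self.snp_idx, "neutral": self.neutral_idx}[loci_class]


@dataclass
class HaplotypePopulation:
    """Phased bi-allelic haplotypes for a cohort.

    ``haplotypes[c]`` is a (2 * n_animals, n_loci) uint8 array for chromosome
    ``c``; rows ``2i`` and ``2i + 1`` are the two haplotypes of animal ``i``.
    Allele 1 is the alternative allele throughout.
    """

    haplotypes: list
    animal_ids: np.ndarray
    genome: GenomeMap | None = None

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        n = len(self.animal_ids)
        for c, h in enumerate(self.haplotypes):
            if h.shape[0] != 2 * n:
                raise ValueError(f"chromosome {c}: expected {2 * n} haplotypes, got {h.shape[0]}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_chromosomes(self) -> int:
        return len(self.haplotypes)

    def n_loci(self, chrom: int | None = None) -> int:
        if chrom is not None:
            return self.haplotypes[chrom].shape[1]
        return sum(h.shape[1] for h in self.haplotypes)

    def dosage_matrix(self, idx_per_chr=None) -> np.ndarray:
        """0/1/2 allele-dosage matrix (animals x loci), optionally restricted."""
        cols = []
        for c, h in enumerate(self.haplotypes):
            d = h[0::2].astype(np.int16) + h[1::2]
            if idx_per_chr is not None:
                d = d[:, np.asarray(idx_per_chr[c], dtype=np.intp)]
            cols.append(d)
        return np.concatenate(cols, axis=1) if cols else np.empty((self.n_animals, 0), np.int16)

    def allele_frequencies(self, idx_per_chr=None) -> np.ndarray:
        """Frequency of allele 1 at each (selected) locus."""
        d = self.dosage_matrix(idx_per_chr)
        return d.mean(axis=0) / 2.0

    def observed_heterozygosity(self, idx_per_chr=None) -> float:
        """Mean per-animal fraction of heterozygous loci."""
        het = []
        for c, h in enumerate(self.haplotypes):
            a, b = h[0::2], h[1::2]
            if idx_per_chr is not None:
                sel = np.asarray(idx_per_chr[c], dtype=np.intp)
                a, b = a[:, sel], b[:, sel]
            het.append(a != b)
        m = np.concatenate(het, axis=1)
        return float(m.mean()) if m.size else 0.0

    def subset(self, rows) -> "HaplotypePopulation":
        rows = np.asarray(rows, dtype=np.intp)
        hap_rows = np.empty(2 * rows.size, dtype=np.intp)
        hap_rows[0::2] = 2 * rows
        hap_rows[1::2] = 2 * rows + 1
        return HaplotypePopulation(
            haplotypes=[h[hap_rows] for h in self.haplotypes],
            animal_ids=self.animal_ids[rows],
            genome=self.genome,
        )


def simulate_founders(
    genome: GenomeMap,
    demography: Demography,
    n_individuals: int,
    sites_per_chr: int,
    seed: int,
) -> HaplotypePopulation:
    """Simulate founder haplotypes and retain segregating sites.

    Per chromosome, an independent coalescent simulation with mutation is
    run; exactly ``sites_per_chr`` segregating bi-allelic sites are retained
    (uniform random subsample when more are available).  Raises if a
    chromosome yields fewer segregating sites than requested.
    """
    if n_individuals < 2:
        raise ValueError("need at least two founder individuals")
    dem = demography.to_msprime()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    msp_seeds = rng.integers(1, 2**31 - 1, size=(genome.n_chromosomes, 2))

    haps, positions = [], []
    for c in range(genome.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_individuals,
            demography=dem,
            sequence_length=genome.physical_length_per_chr,
            recombination_rate=genome.recombination_rate,
            random_seed=int(msp_seeds[c, 0]),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=genome.mutation_rate,
            random_seed=int(msp_seeds[c, 1]),
            model=msprime.BinaryMutationModel(),
        )
        gm = mts.genotype_matrix()  # (sites, 2n)
        pos = np.array([s.position for s in mts.sites()])
        # restrict to segregating bi-allelic sites
        gm = np.minimum(gm, 1).astype(np.uint8)
        counts = gm.sum(axis=1)
        keep = (counts > 0) & (counts < gm.shape[1])
        gm, pos = gm[keep], pos[keep]
        # collapse duplicate integer positions (keep first)
        ipos = np.floor(pos).astype(np.int64)
        _, first = np.unique(ipos, return_index=True)
        gm, ipos = gm[first], ipos[first]
        if gm.shape[0] < sites_per_chr:
            raise ValueError(
                f"chromosome {c}: only {gm.shape[0]} segregating sites available, "
                f"{sites_per_chr} requested"
            )
        sel = np.sort(rng.choice(gm.shape[0], size=sites_per_chr, replace=False))
        haps.append(np.ascontiguousarray(gm[sel].T))  # (2n, sites)
        positions.append(ipos[sel])

    return HaplotypePopulation(
        haplotypes=haps,
        animal_ids=np.arange(1, n_individuals + 1),
        genome=genome.with_positions(positions),
    )


def partition_loci(
    pop: HaplotypePopulation,
    counts_per_chr: tuple,
    seed: int,
) -> LociPartition:
    """Randomly partition retained sites into disjoint QTL / SNP / neutral sets."""
    n_qtl, n_snp, n_neutral = counts_per_chr
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    qtl, snp, neutral = [], [], []
    for c in range(pop.n_chromosomes):
        n_sites = pop.n_loci(c)
        if n_qtl + n_snp + n_neutral > n_sites:
            raise ValueError(
                f"chromosome {c}: requested {n_qtl + n_snp + n_neutral} loci "
                f"but only {n_sites} sites retained"
            )
        perm = rng.permutation(n_sites)
        qtl.append(np.sort(perm[:n_qtl]))
        snp.append(np.sort(perm[n_qtl : n_qtl + n_snp]))
        neutral.append(np.sort(perm[n_qtl + n_snp : n_qtl + n_snp + n_neutral]))
    return LociPartition(qtl_idx=tuple(qtl), snp_idx=tuple(snp), neutral_idx=tuple(neutral))


def export_snp_genotypes(pop: HaplotypePopulation, partition: LociPartition, path: str) -> None:
    """Write SNP dosages as a plain 0/1/2 matrix with an animal-id header row."""
    dos = pop.dosage_matrix(partition.snp_idx)
    with open(path, "w") as fh:
        fh.write("\t".join(str(i) for i in pop.animal_ids.tolist()) + "\n")
        for row in dos.T:  # one SNP per line
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def save_population(pop: HaplotypePopulation, directory: str, partition: LociPartition | None = None) -> None:
    """Persist haplotypes (one matrix per chromosome) with a JSON sidecar."""
    os.makedirs(directory, exist_ok=True)
    meta = {
        "animal_ids": pop.animal_ids.tolist(),
        "n_chromosomes": pop.n_chromosomes,
        "positions": [np.asarray(p).tolist() for p in pop.genome.positions] if pop.genome and pop.genome.positions else None,
        "genome": None
        if pop.genome is None
        else {
            "n_chromosomes": pop.genome.n_chromosomes,
            "physical_length_per_chr": pop.genome.physical_length_per_chr,
            "recombination_rate": pop.genome.recombination_rate,
            "mutation_rate": pop.genome.mutation_rate,
        },
        "partition": None
        if partition is None
        else {
            "qtl": [np.asarray(i).tolist() for i in partition.qtl_idx],
            "snp": [np.asarray(i).tolist() for i in partition.snp_idx],
            "neutral": [np.asarray(i).tolist() for i in partition.neutral_idx],
        },
    }
    with open(os.path.join(directory, "population.json"), "w") as fh:
        json.dump(meta, fh)
    for c, h in enumerate(pop.haplotypes):
        np.save(os.path.join(directory, f"chr{c}.npy"), h)


def load_population(directory: str):
    """Inverse of :func:`save_population`; returns (population, partition | None)."""
    with open(os.path.join(directory, "population.json")) as fh:
        meta = json.load(fh)
    haps = [np.load(os.path.join(directory, f"chr{c}.npy")) for c in range(meta["n_chromosomes"])]
    genome = None
    if meta["genome"] is not None:
        genome = GenomeMap(
            n_chromosomes=meta["genome"]["n_chromosomes"],
            physical_length_per_chr=meta["genome"]["physical_length_per_chr"],
            recombination_rate=meta["genome"]["recombination_rate"],
            mutation_rate=meta["genome"]["mutation_rate"],
        )
        if meta["positions"] is not None:
            genome = genome.with_positions([np.asarray(p, dtype=np.int64) for p in meta["positions"]])
    pop = HaplotypePopulation(haplotypes=haps, animal_ids=np.asarray(meta["animal_ids"]), genome=genome)
    part = None
    if meta["partition"] is not None:
        part = LociPartition(
            qtl_idx=tuple(np.asarray(i) for i in meta["partition"]["qtl"]),
            snp_idx=tuple(np.asarray(i) for i in meta["partition"]["snp"]),
            neutral_idx=tuple(np.asarray(i) for i in meta["partition"]["neutral"]),
        )
    return pop, part
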