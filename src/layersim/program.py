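"""Year-cycle scheduler composing founders, traits, inheritance, evaluation,
and selection into the breeding scenarios.

Scenarios: PTS (conventional truncation), GTS (genomic truncation), GTSMF
(GTS + minimum-progeny-inbreeding mating), GOCS / UGOCS (optimal
contributions at a target trigonometric degree), RANDOM (random selection
control).  Every program starts from a conventional burn-in; with a shared
replicate seed, scenarios are bit-identical through the end of burn-in.

Timeline conventions (0.5-year grid):
  * conventional rounds run at integer years; candidates are one year old
    at selection, so the generation interval is 1.0;
  * genomic rounds run every half year; sires are selected at age 0.5
    (genotyped, no own phenotype) and dams at age 1.0 (first two trait
    phenotypes recorded), realizing a generation interval of 0.75.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import founders as fnd
from . import traits as tr
from .evaluation import MMEProblem, accuracy, pedigree_kinship, single_step_kinship, solve_mme
from .inheritance import FEMALE, MALE, PedigreeTable, make_offspring
from .kinship import a_submatrix, inbreeding_meuwissen_luo
from .ocs import (
    OCSProblem,
    min_inbreeding_matings,
    random_mating,
    solve_ocs,
    truncation_select,
)

__all__ = [
    "ScenarioConfig",
    "PopulationState",
    "YearRecord",
    "SCENARIOS",
    "genotyping_policy",
    "initialize_state",
    "run_year_conventional",
    "run_year_genomic",
    "run_program",
]

SCENARIOS = ("PTS", "GTS", "GTSMF", "GOCS", "UGOCS", "RANDOM")
GENOMIC_SCENARIOS = ("GTS", "GTSMF", "GOCS", "UGOCS")


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one breeding-program scenario (reduced-scale defaults)."""

    scenario: str = "PTS"
    n_sires: int = 12
    n_dams: int = 108
    degrees: float = 45.0
    female_per_dam: int = 9
    male_per_dam: int = 4
    burn_in_years: int = 5
    eval_years: int = 10
    # genome / founders
    n_chromosomes: int = 5
    physical_length_per_chr: float = 2.0e6
    #: reduced-scale default keeps the realistic ~0.77 Morgan per chromosome
    #: on a short physical map; the full-scale preset pins the real rate
    recombination_rate: float = 3.85e-7
    mutation_rate: float = 5.0e-8
    sites_per_chr: int = 100
    qtl_per_chr: int = 20
    snp_per_chr: int = 40
    neutral_per_chr: int = 40
    n_founders: int = 250
    demography_epochs: tuple = fnd.DEFAULT_EPOCHS
    demography_refine: int = 0
    # traits
    heritabilities: tuple = tuple(tr.HERITABILITIES)
    genetic_correlations: tuple = tuple(tr.GENETIC_CORRELATIONS)
    index_weights: tuple = tuple(tr.INDEX_WEIGHTS)
    t3_lag_years: float = 1.0
    # evaluation
    evaluation_mode: str = "blup"  # blup | proxy | random
    proxy_accuracy: float = 0.7
    solver_tol: float = 1e-6
    solver_maxiter: int = 20000
    # genomic programs
    genotyping_generations_back: int = 4
    # optimal contributions
    sire_range: tuple = (20, 200)  # UGOCS window
    ea_mu: int = 40
    ea_lambda: int = 160
    ea_generations: int = 2000
    ea_stagnation: int = 200
    # bookkeeping
    track_pedigree_f: bool = True

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_dams % self.n_sires != 0:
            raise ValueError("n_dams must be a multiple of n_sires (equal quotas)")
        if self.evaluation_mode not in ("blup", "proxy", "random"):
            raise ValueError(f"unknown evaluation mode {self.evaluation_mode!r}")
        q, s, n = self.qtl_per_chr, self.snp_per_chr, self.neutral_per_chr
        if q + s + n > self.sites_per_chr:
            raise ValueError("loci classes exceed retained sites per chromosome")

    @property
    def candidates_per_cycle(self) -> int:
        return self.n_dams * (self.female_per_dam + self.male_per_dam)

    @property
    def is_genomic(self) -> bool:
        return self.scenario in GENOMIC_SCENARIOS

    @property
    def quota(self) -> int:
        return self.n_dams // self.n_sires

    def genome(self) -> fnd.GenomeMap:
        return fnd.GenomeMap(
            n_chromosomes=self.n_chromosomes,
            physical_length_per_chr=self.physical_length_per_chr,
            recombination_rate=self.recombination_rate,
            mutation_rate=self.mutation_rate,
        )

    def demography(self) -> fnd.Demography:
        return fnd.Demography(epochs=tuple(tuple(e) for e in self.demography_epochs), refine_steps=self.demography_refine)

    def ea_params(self) -> dict:
        return dict(
            mu=self.ea_mu,
            lam=self.ea_lambda,
            n_gen=self.ea_generations,
            stagnation=self.ea_stagnation,
        )

    @classmethod
    def full_scale(cls, **overrides) -> "ScenarioConfig":
        """The published program dimensions (39 chromosomes, 1,080 dams...)."""
        base = dict(
            n_sires=40,
            n_dams=1080,
            burn_in_years=10,
            eval_years=20,
            n_chromosomes=39,
            physical_length_per_chr=1.2e9 / 39,
            recombination_rate=2.5e-8,
            sites_per_chr=2250,
            qtl_per_chr=250,
            snp_per_chr=1000,
            neutral_per_chr=1000,
            n_founders=2500,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class YearRecord:
    """Per-time-point cohort summary consumed by the metrics module."""

    time: float
    n_candidates: int
    mean_tbv: float
    sd_tbv: float
    genic_sd_index: float
    genic_sd_t1: float
    genic_sd_t2: float
    genic_sd_t3: float
    het_snp: float
    het_qtl: float
    het_neutral: float
    pedigree_f: float
    accuracy: float
    accuracy_male: float
    accuracy_female: float
    n_sires_used: int
    n_genotyped: int
    generation_interval: float


@dataclass
class PopulationState:
    """Live simulation state: pedigree, trait stores, cohorts, genotype bank."""

    config: ScenarioConfig
    genome: fnd.GenomeMap
    partition: fnd.LociPartition
    arch: tr.TraitArchitecture
    ped: PedigreeTable
    tbv: np.ndarray  # (N, 3)
    phen: np.ndarray  # (N, 3)
    avail: np.ndarray  # (N, 3) availability times
    cohorts: dict  # birth time -> HaplotypePopulation
    snp_bank: dict = field(default_factory=dict)  # pedigree row -> SNP dosages
    selected_history: list = field(default_factory=list)  # (time, rows)
    records: list = field(default_factory=list)
    prev_solution: np.ndarray | None = None
    time: float = 0.0

    @property
    def tbv_index(self) -> np.ndarray:
        return self.tbv @ np.asarray(self.config.index_weights)

    def cohort_rows(self, t: float) -> np.ndarray:
        return self.cohorts[t].animal_ids - 1

    def latest_cohort_time(self, at_or_before: float) -> float:
        times = [t for t in self.cohorts if t <= at_or_before + 1e-9]
        if not times:
            raise ValueError(f"no cohort available at or before {at_or_before}")
        return max(times)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _derive_rng(seed: int, *keys) -> np.random.Generator:
    """Counter-style stream derivation: one child stream per (seed, keys)."""
    ent = [int(seed)] + [zlib.crc32(k.encode()) if isinstance(k, str) else int(round(k * 2)) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ent))


def _derive_int(seed: int, *keys) -> int:
    return int(_derive_rng(seed, *keys).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# initialization


def initialize_state(config: ScenarioConfig, seed: int) -> PopulationState:
    """Simulate founders, sample the trait architecture, seed the pedigree."""
    genome = config.genome()
    pop = fnd.simulate_founders(
        genome,
        config.demography(),
        config.n_founders,
        config.sites_per_chr,
        seed=_derive_int(seed, "founders"),
    )
    genome = pop.genome
    partition = fnd.partition_loci(
        pop,
        (config.qtl_per_chr, config.snp_per_chr, config.neutral_per_chr),
        seed=_derive_int(seed, "partition"),
    )
    qtl_freqs = pop.allele_frequencies(partition.qtl_idx)
    arch = tr.sample_effects(
        partition,
        qtl_freqs,
        tr.base_genetic_covariance(np.asarray(config.heritabilities), np.asarray(config.genetic_correlations)),
        seed=_derive_int(seed, "effects"),
    )
    n = config.n_founders
    sexes = np.where(np.arange(n) % 2 == 0, FEMALE, MALE).astype(np.int8)
    ped = PedigreeTable()
    ped.add(np.zeros(n, np.int64), np.zeros(n, np.int64), sexes, 0.0)
    tbv = tr.true_genetic_values(pop, arch).tbv
    rng = _derive_rng(seed, "founder-phen")
    phen = tbv + rng.standard_normal(tbv.shape) * np.sqrt(arch.residual_var)
    avail = _availability(sexes, birth_time=0.0, t3=False)
    state = PopulationState(
        config=config,
        genome=genome,
        partition=partition,
        arch=arch,
        ped=ped,
        tbv=tbv,
        phen=phen,
        avail=avail,
        cohorts={0.0: pop},
    )
    return state


def _availability(sexes: np.ndarray, birth_time, t3: bool) -> np.ndarray:
    """Availability times: females get T1 at age 0.5 and T2 at age 1.0;
    T3 (recorded only for selected dams) is set later; males never recorded."""
    n = sexes.size
    birth = np.full(n, birth_time, dtype=float) if np.isscalar(birth_time) else np.asarray(birth_time, float)
    avail = np.full((n, 3), np.inf)
    fem = sexes == FEMALE
    avail[fem, 0] = birth[fem] + 0.5
    avail[fem, 1] = birth[fem] + 1.0
    return avail


# ---------------------------------------------------------------------------
# evaluation glue


def _snp_dosages(state: PopulationState, rows: np.ndarray) -> np.ndarray:
    """SNP dosage matrix for pedigree rows, served from the genotype bank."""
    out = np.empty((rows.size, sum(len(i) for i in state.partition.snp_idx)), dtype=np.uint8)
    missing = [r for r in rows.tolist() if r not in state.snp_bank]
    if missing:
        missing_set = set(missing)
        for t, pop in state.cohorts.items():
            c_rows = pop.animal_ids - 1
            hit = [i for i, r in enumerate(c_rows.tolist()) if r in missing_set]
            if hit:
                dos = pop.subset(np.asarray(hit)).dosage_matrix(state.partition.snp_idx).astype(np.uint8)
                for k, i in enumerate(hit):
                    state.snp_bank[int(c_rows[i])] = dos[k]
        still = [r for r in missing if r not in state.snp_bank]
        if still:
            raise KeyError(f"no stored haplotypes or genotypes for pedigree rows {still[:5]}")
    for i, r in enumerate(rows.tolist()):
        out[i] = state.snp_bank[r]
    return out


def genotyping_policy(state: PopulationState, config: ScenarioConfig, male_candidate_rows: np.ndarray) -> np.ndarray:
    """Genotyped set for one genomic evaluation: the current male candidates
    plus the selected sires and dams of the previous <= 4 generations."""
    back = config.genotyping_generations_back
    prev = [rows for (_, rows) in state.selected_history[-back:]]
    parts = [np.asarray(male_candidate_rows, np.int64)] + [np.asarray(p, np.int64) for p in prev]
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.int64)


def _evaluate(
    state: PopulationState,
    t: float,
    seed: int,
    genotyped_rows: np.ndarray | None,
) -> tuple[np.ndarray, int]:
    """Index values for every animal in the pedigree at time t.

    Returns (index, n_genotyped).  Mode 'blup' runs the (ss)GBLUP MME;
    'proxy' returns noised true values at a preset accuracy (structural
    runs only); 'random' returns uniform noise (the RANDOM control).
    """
    cfg = state.config
    n = state.ped.n
    weights = np.asarray(cfg.index_weights)
    n_geno = 0 if genotyped_rows is None else int(np.asarray(genotyped_rows).size)
    if cfg.evaluation_mode == "random":
        return _derive_rng(seed, "random-index", t).random(n), n_geno
    if cfg.evaluation_mode == "proxy":
        rng = _derive_rng(seed, "proxy-index", t)
        acc = cfg.proxy_accuracy
        gvar = np.diag(state.arch.base_genetic_cov)
        noise = rng.standard_normal((n, 3)) * np.sqrt(gvar * (1.0 / acc**2 - 1.0))
        return (state.tbv + noise) @ weights, n_geno
    y = np.where(state.avail <= t + 1e-9, state.phen, np.nan)
    if genotyped_rows is not None and np.asarray(genotyped_rows).size:
        genotyped_rows = np.asarray(genotyped_rows, np.int64)
        geno = _snp_dosages(state, genotyped_rows)
        kin = single_step_kinship(state.ped, genotyped_rows + 1, geno)
    else:
        kin = pedigree_kinship(state.ped)
    problem = MMEProblem(
        phenotypes=y,
        genetic_cov=state.arch.base_genetic_cov,
        residual_var=state.arch.residual_var,
        kinship=kin,
    )
    x0 = None
    if state.prev_solution is not None:
        n_old = (state.prev_solution.size - 3) // 3
        x0 = np.zeros(3 + 3 * n)
        x0[:3] = state.prev_solution[:3]
        for u in range(3):
            x0[3 + u * n : 3 + u * n + n_old] = state.prev_solution[3 + u * n_old : 3 + (u + 1) * n_old]
    ebv = solve_mme(problem, tol=cfg.solver_tol, maxiter=cfg.solver_maxiter, method="pcg", x0=x0)
    state.prev_solution = np.concatenate([ebv.means, ebv.ebv.T.ravel()])
    return ebv.ebv @ weights, n_geno


# ---------------------------------------------------------------------------
# rounds


def _spawn_cohort(state, sire_rows, dam_rows, t: float, seed: int):
    """Mate (per-mating parent rows), creating the new candidate cohort."""
    cfg = state.config
    f, m = cfg.female_per_dam, cfg.male_per_dam
    per = f + m
    rep_s = np.repeat(sire_rows, per)
    rep_d = np.repeat(dam_rows, per)
    sexes = np.tile(np.concatenate([np.full(f, FEMALE, np.int8), np.full(m, MALE, np.int8)]), sire_rows.size)
    parent_rows = np.unique(np.concatenate([sire_rows, dam_rows]))
    parent_pop = _gather_pop(state, parent_rows)
    local = {int(r): i for i, r in enumerate(parent_pop.animal_ids - 1)}
    loc_s = np.array([local[int(r)] for r in rep_s], np.int64)
    loc_d = np.array([local[int(r)] for r in rep_d], np.int64)
    rng = _derive_rng(seed, "meiosis", t)
    cohort = make_offspring(parent_pop, state.ped, loc_s, loc_d, sexes, t, rng)
    # trait bookkeeping
    tbv = tr.true_genetic_values(cohort, state.arch).tbv
    rngp = _derive_rng(seed, "phen", t)
    phen = tbv + rngp.standard_normal(tbv.shape) * np.sqrt(state.arch.residual_var)
    state.tbv = np.vstack([state.tbv, tbv])
    state.phen = np.vstack([state.phen, phen])
    state.avail = np.vstack([state.avail, _availability(sexes, t, t3=False)])
    state.cohorts[t] = cohort
    return cohort


def _gather_pop(state: PopulationState, rows: np.ndarray) -> fnd.HaplotypePopulation:
    """Collect one HaplotypePopulation for arbitrary pedigree rows from the
    stored cohorts (raises if any animal's haplotypes were discarded)."""
    rows = np.asarray(rows, np.int64)
    want = set(rows.tolist())
    pieces = []
    for t in sorted(state.cohorts):
        pop = state.cohorts[t]
        c_rows = pop.animal_ids - 1
        hit = np.flatnonzero(np.isin(c_rows, rows))
        if hit.size:
            pieces.append(pop.subset(hit))
            want -= set(c_rows[hit].tolist())
    if want:
        raise KeyError(f"haplotypes discarded for rows {sorted(want)[:5]}")
    haps = [np.concatenate([p.haplotypes[c] for p in pieces]) for c in range(state.genome.n_chromosomes)]
    ids = np.concatenate([p.animal_ids for p in pieces])
    order = np.argsort(ids)
    merged = fnd.HaplotypePopulation(
        haplotypes=[h.reshape(-1, 2, h.shape[1])[order].reshape(-1, h.shape[1]) for h in haps],
        animal_ids=ids[order],
        genome=state.genome,
    )
    # reorder to match requested rows
    pos = {int(r): i for i, r in enumerate(merged.animal_ids - 1)}
    sel = np.array([pos[int(r)] for r in rows], np.int64)
    return merged.subset(sel)


def _record_cohort(state, t, cohort, acc_all, acc_m, acc_f, n_sires_used, n_geno):
    cfg = state.config
    rows = cohort.animal_ids - 1
    tbv_idx = state.tbv[rows] @ np.asarray(cfg.index_weights)
    freqs = cohort.allele_frequencies(state.partition.qtl_idx)
    gv = tr.genic_variance(freqs, state.arch)
    gvi = tr.genic_variance(freqs, state.arch, index_weights=np.asarray(cfg.index_weights))
    if cfg.track_pedigree_f:
        fped = float(inbreeding_meuwissen_luo(state.ped)[rows].mean())
    else:
        fped = float("nan")
    parent_age = float(
        np.mean(
            np.concatenate(
                [
                    t - state.ped.birth_time[state.ped.sire_id[rows] - 1],
                    t - state.ped.birth_time[state.ped.dam_id[rows] - 1],
                ]
            )
        )
    )
    state.records.append(
        YearRecord(
            time=t,
            n_candidates=cohort.n_animals,
            mean_tbv=float(tbv_idx.mean()),
            sd_tbv=float(tbv_idx.std(ddof=1)),
            genic_sd_index=float(np.sqrt(gvi)),
            genic_sd_t1=float(np.sqrt(gv[0])),
            genic_sd_t2=float(np.sqrt(gv[1])),
            genic_sd_t3=float(np.sqrt(gv[2])),
            het_snp=cohort.observed_heterozygosity(state.partition.snp_idx),
            het_qtl=cohort.observed_heterozygosity(state.partition.qtl_idx),
            het_neutral=cohort.observed_heterozygosity(state.partition.neutral_idx),
            pedigree_f=fped,
            accuracy=acc_all,
            accuracy_male=acc_m,
            accuracy_female=acc_f,
            n_sires_used=n_sires_used,
            n_genotyped=n_geno,
            generation_interval=parent_age,
        )
    )


def _mark_t3(state, dam_rows, t):
    """Record the late trait for newly selected dams (enters evaluations
    after the configured lag)."""
    state.avail[dam_rows, 2] = t + state.config.t3_lag_years


def _prune(state, t):
    """Drop haplotypes of cohorts that can no longer become parents, and
    bank entries outside the genotyping policy horizon."""
    for tc in [tc for tc in state.cohorts if tc < t - 1.6]:
        del state.cohorts[tc]
    back = state.config.genotyping_generations_back
    keep = set()
    for (_, rows) in state.selected_history[-(back + 1) :]:
        keep.update(int(r) for r in rows)
    for pop in state.cohorts.values():
        keep.update(int(r) for r in (pop.animal_ids - 1))
    for r in [r for r in state.snp_bank if r not in keep]:
        del state.snp_bank[r]


def run_year_conventional(state: PopulationState, seed: int, random_index: bool = False) -> PopulationState:
    """One conventional year: evaluate, truncation-select, random equal mating."""
    cfg = state.config
    t = state.time + 1.0
    cand_t = state.latest_cohort_time(t - 1.0)
    cohort = state.cohorts[cand_t]
    cand_rows = cohort.animal_ids - 1
    mode_seed = _derive_int(seed, "round", t)
    if random_index:
        index, n_geno = _derive_rng(mode_seed, "random-index", t).random(state.ped.n), 0
    else:
        index, n_geno = _evaluate(state, t, mode_seed, genotyped_rows=None)
    is_male = state.ped.sex[cand_rows] == MALE
    tbv_idx = state.tbv_index
    acc = accuracy(index[cand_rows], tbv_idx[cand_rows])
    acc_m = accuracy(index[cand_rows[is_male]], tbv_idx[cand_rows[is_male]])
    acc_f = accuracy(index[cand_rows[~is_male]], tbv_idx[cand_rows[~is_male]])
    fem, mal = truncation_select(index[cand_rows], is_male, cfg.n_dams, cfg.n_sires)
    dam_rows, sire_rows = cand_rows[fem], cand_rows[mal]
    _mark_t3(state, dam_rows, t)
    plan = random_mating(sire_rows, np.full(cfg.n_sires, cfg.quota), dam_rows, seed=_derive_int(mode_seed, "mating", t))
    new = _spawn_cohort(state, plan.sires, plan.dams, t, seed=mode_seed)
    selected = np.unique(np.concatenate([dam_rows, sire_rows]))
    _snp_dosages(state, selected)  # bank genotypes while haplotypes are live
    state.selected_history.append((t, selected))
    _record_cohort(state, t, new, acc, acc_m, acc_f, int(np.unique(plan.sires).size), n_geno)
    state.time = t
    _prune(state, t)
    return state


def _select_males_genomic(state, index, sire_cand_rows, dam_rows, seed):
    """Scenario-specific male selection for one genomic round.

    Returns (per-mating sire rows, per-mating dam rows, n_sires_used).
    """
    cfg = state.config
    m = cfg.n_dams
    if cfg.scenario in ("GTS", "GTSMF", "RANDOM"):
        order = np.lexsort((sire_cand_rows, -index[sire_cand_rows]))
        sire_rows = sire_cand_rows[order[: cfg.n_sires]]
        quotas = np.full(cfg.n_sires, cfg.quota)
        if cfg.scenario == "GTSMF":
            sel = np.concatenate([sire_rows, dam_rows])
            a_sel = a_submatrix(state.ped, sel + 1).values
            plan = min_inbreeding_matings(
                np.arange(cfg.n_sires),
                quotas,
                np.arange(cfg.n_sires, sel.size),
                a_sel,
                seed=_derive_int(seed, "minf-mating"),
            )
            return sel[plan.sires], sel[plan.dams], cfg.n_sires
        plan = random_mating(sire_rows, quotas, dam_rows, seed=_derive_int(seed, "mating"))
        return plan.sires, plan.dams, cfg.n_sires
    # optimal contributions (GOCS / UGOCS)
    cand = np.concatenate([dam_rows, sire_cand_rows])
    a_cand = a_submatrix(state.ped, cand + 1).values
    is_male = np.zeros(cand.size, bool)
    is_male[dam_rows.size :] = True
    if cfg.scenario == "GOCS":
        cap, srange = cfg.quota, (cfg.n_sires, cfg.n_sires)
    else:  # UGOCS
        cap, srange = m, cfg.sire_range
    problem = OCSProblem(
        index=index[cand],
        a=a_cand,
        is_male=is_male,
        n_matings=m,
        cap=cap,
        sire_range=srange,
        degrees=cfg.degrees,
        ids=cand + 1,
    )
    sol = solve_ocs(problem, seed=_derive_int(seed, "ocs"), ea_params=cfg.ea_params())
    used_rows, counts = sol.sire_rows(problem)
    sire_rows = cand[used_rows]
    plan = random_mating(sire_rows, counts, dam_rows, seed=_derive_int(seed, "mating"))
    return plan.sires, plan.dams, sol.sires_used


def run_year_genomic(state: PopulationState, seed: int) -> PopulationState:
    """One genomic half-year round: genotype, evaluate (ssGBLUP), select
    sires at 0.5 y and dams at 1 y, mate, and record the new cohort."""
    cfg = state.config
    t = state.time + 0.5
    sire_cohort_t = state.latest_cohort_time(t - 0.5)
    dam_cohort_t = state.latest_cohort_time(t - 1.0)
    sire_pop = state.cohorts[sire_cohort_t]
    dam_pop = state.cohorts[dam_cohort_t]
    sire_cand_rows = (sire_pop.animal_ids - 1)[state.ped.sex[sire_pop.animal_ids - 1] == MALE]
    dam_cand_rows = (dam_pop.animal_ids - 1)[state.ped.sex[dam_pop.animal_ids - 1] == FEMALE]
    mode_seed = _derive_int(seed, "round", t)
    genotyped = genotyping_policy(state, cfg, sire_cand_rows)
    if cfg.scenario == "RANDOM":
        index = _derive_rng(mode_seed, "random-index", t).random(state.ped.n)
        n_geno = genotyped.size
    else:
        index, n_geno = _evaluate(state, t, mode_seed, genotyped_rows=genotyped)
    cand_rows = np.concatenate([sire_cand_rows, dam_cand_rows])
    tbv_idx = state.tbv_index
    acc = accuracy(index[cand_rows], tbv_idx[cand_rows])
    acc_m = accuracy(index[sire_cand_rows], tbv_idx[sire_cand_rows])
    acc_f = accuracy(index[dam_cand_rows], tbv_idx[dam_cand_rows])
    fem, _ = truncation_select(
        index[dam_cand_rows], np.zeros(dam_cand_rows.size, bool), cfg.n_dams, 0
    )
    dam_rows = dam_cand_rows[fem]
    _mark_t3(state, dam_rows, t)
    mate_s, mate_d, n_sires_used = _select_males_genomic(state, index, sire_cand_rows, dam_rows, mode_seed)
    new = _spawn_cohort(state, mate_s, mate_d, t, seed=mode_seed)
    selected = np.unique(np.concatenate([dam_rows, np.unique(mate_s)]))
    _snp_dosages(state, selected)
    state.selected_history.append((t, selected))
    _record_cohort(state, t, new, acc, acc_m, acc_f, n_sires_used, n_geno)
    state.time = t
    _prune(state, t)
    return state


def run_program(config: ScenarioConfig, replicate_seed: int) -> tuple[pd.DataFrame, PopulationState]:
    """Run burn-in plus evaluation years for one replicate.

    Burn-in is conventional truncation on BLUP for every scenario, so two
    scenarios sharing ``replicate_seed`` (and dimensions) are identical
    through year ``burn_in_years``.
    """
    state = initialize_state(config, replicate_seed)
    for _ in range(config.burn_in_years):
        run_year_conventional(state, replicate_seed)
    horizon = config.burn_in_years + config.eval_years
    if config.is_genomic:
        while state.time < horizon - 1e-9:
            run_year_genomic(state, replicate_seed)
    else:
        random_index = config.scenario == "RANDOM"
        while state.time < horizon - 1e-9:
            run_year_conventional(state, replicate_seed, random_index=random_index)
    return state.records_frame(), state
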