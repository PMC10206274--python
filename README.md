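# layersim

Stochastic simulation of an intense layer-chicken breeding program:
conventional (pedigree BLUP) truncation selection, genomic (ssGBLUP)
truncation selection with or without minimum-progeny-inbreeding mate
allocation, and genomic optimal contribution selection (OCS) across
"trigonometric penalty degrees" between maximal gain (0°) and minimal
group coancestry (90°). Programs are compared by genetic gain, genic
variance, conversion efficiency, rate of inbreeding, effective population
size, and accuracy of selection.

## What is simulated

* **Founders** — coalescent base-population haplotypes (msprime) under a
  shrinking effective-size history (recent Ne 100, ancient Ne 500,000);
  retained segregating sites are partitioned into disjoint QTL / SNP /
  neutral sets (full scale: 39 chromosomes, 30 Morgans, 2,250 sites per
  chromosome → 9,750 QTL + 39,000 SNP + 39,000 neutral).
* **Traits** — three correlated, purely additive traits (h² 0.18 / 0.22 /
  0.25; genetic correlations 0.75 / 0.70 / 0.60), selection index weights
  0.20 / 0.35 / 0.45. Phenotypes on females only; the late trait is
  recorded only for selected dams.
* **Inheritance** — Poisson crossovers on the genetic map, no mutation
  after the base population; each of 1,080 dams contributes 9 female + 4
  male candidates (14,040 per cycle).
* **Evaluation** — three-trait BLUP / single-step GBLUP mixed-model
  equations with known variance components, solved by block-preconditioned
  conjugate gradients (dense reference path for tests). Genotypes cover
  male candidates plus up to four generations of selected parents (at most
  8,800 / 9,120 per evaluation for 40 / 120 sires).
* **Selection** — truncation, exact minimum-progeny-inbreeding mate
  assignment, and an evolutionary algorithm over integer mating-count
  vectors for OCS (male side only, female contributions fixed), targeting
  a position on the normalized gain/coancestry frontier.
* **Scheduler** — 10-year conventional burn-in shared across scenarios,
  then 20 evaluation years; conventional programs run one round per year
  (generation interval 1.0), genomic programs two rounds per year (sires
  used at age 0.5, dams at 1.0; generation interval 0.75). A RANDOM
  scenario serves as a drift control for validating Ne estimates.

## Command line

```bash
# base-population haplotypes + locus partition
layersim simulate-founders --config cfg.yaml --seed 1 --out founders/

# run a scenario (PTS, GTS, GTSMF, GOCS, UGOCS, RANDOM)
layersim run --scenario GOCS --sires 40 --degrees 65 --replicates 10 \
             --config cfg.yaml --seed 1 --out results/gocs65/

# summarize a finished run directory (gain, genic SD, conversion
# efficiency, dF/year, Ne, accuracy; mean and replicate SD)
layersim metrics --in results/gocs65/
```

`cfg.yaml` holds `ScenarioConfig` keys (unknown keys are rejected); an
empty file gives the reduced-scale defaults, and
`ScenarioConfig.full_scale()` in Python gives the published dimensions.
Every run writes per-replicate records, a combined long CSV, a mean (SD)
summary, and a JSON manifest with the derived per-replicate seeds.

## Layout

```
src/layersim/
  founders.py     coalescent founders, genome map, loci partition
  traits.py       trait architecture, TBV, phenotypes, genic variance
  inheritance.py  meiosis (numba), offspring, pedigree
  kinship.py      A (tabular/Colleau), Meuwissen–Luo F, A⁻¹, G, H
  evaluation.py   multi-trait BLUP / ssGBLUP solver, index, accuracy
  ocs.py          truncation, mate allocation, OCS frontier EA
  program.py      scenario scheduler and configuration
  metrics.py      normalization, conversion efficiency, dF, Ne, L
  cli_io.py       YAML config, replicate orchestration, CLI
```
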