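"""Correlated additive traits: QTL effects, true genetic values, phenotypes,
and genic variance.

Three purely additive traits with base phenotypic variance 1 per trait.
The genetic covariance implied by the heritabilities and genetic
correlations is imposed exactly on the founder genic covariance by a linear
transform of the sampled QTL effects.  Residual covariances across traits
are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founders import HaplotypePopulation, LociPartition

__all__ = [
    "HERITABILITIES",
    "GENETIC_CORRELATIONS",
    "INDEX_WEIGHTS",
    "base_genetic_covariance",
    "TraitArchitecture",
    "TraitValues",
    "sample_effects",
    "true_genetic_values",
    "simulate_phenotypes",
    "genic_variance",
]

HERITABILITIES = np.array([0.18, 0.22, 0.25])
#: genetic correlations (T1-T2, T2-T3, T1-T3)
GENETIC_CORRELATIONS = np.array([0.75, 0.70, 0.60])
INDEX_WEIGHTS = np.array([0.20, 0.35, 0.45])


def base_genetic_covariance(
    h2=HERITABILITIES, corr=GENETIC_CORRELATIONS
) -> np.ndarray:
    """3x3 genetic covariance at base phenotypic variance 1 per trait."""
    h2 = np.asarray(h2, dtype=float)
    sd = np.sqrt(h2)
    r12, r23, r13 = corr
    c = np.diag(h2).astype(float)
    c[0, 1] = c[1, 0] = r12 * sd[0] * sd[1]
    c[1, 2] = c[2, 1] = r23 * sd[1] * sd[2]
    c[0, 2] = c[2, 0] = r13 * sd[0] * sd[2]
    return c


@dataclass
class TraitArchitecture:
    """QTL effects per trait plus base genetic / residual covariances."""

    effects: np.ndarray  # (n_qtl, n_traits)
    base_genetic_cov: np.ndarray  # (n_traits, n_traits)
    residual_cov: np.ndarray  # diagonal (n_traits, n_traits)
    partition: LociPartition | None = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        self.base_genetic_cov = np.asarray(self.base_genetic_cov, dtype=float)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        off = self.residual_cov - np.diag(np.diag(self.residual_cov))
        if np.any(off != 0):
            raise ValueError("residual covariance must be diagonal")
        if not np.allclose(self.base_genetic_cov, self.base_genetic_cov.T):
            raise ValueError("genetic covariance must be symmetric")

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]

    @property
    def residual_var(self) -> np.ndarray:
        return np.diag(self.residual_cov)


@dataclass
class TraitValues:
    """True breeding values and (optionally) phenotypes per animal per trait.

    ``available_from[i, t]`` is the earliest time the record of animal ``i``
    for trait ``t`` can enter an evaluation (``inf`` = never recorded).
    """

    tbv: np.ndarray  # (n, n_traits)
    phenotypes: np.ndarray | None = None
    available_from: np.ndarray | None = None

    @property
    def n_animals(self) -> int:
        return self.tbv.shape[0]


def sample_effects(
    partition: LociPartition,
    founder_freqs: np.ndarray,
    target_cov: np.ndarray,
    seed: int,
    residual_var: np.ndarray | None = None,
) -> TraitArchitecture:
    """Draw multivariate-normal QTL effects and rescale them so the founder
    genic covariance equals ``target_cov`` exactly.

    ``founder_freqs`` are allele-1 frequencies at the QTL, founder order.
    """
    p = np.asarray(founder_freqs, dtype=float)
    target_cov = np.asarray(target_cov, dtype=float)
    n_traits = target_cov.shape[0]
    n_q = p.size
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if np.all(target_cov == 0):
        eff = np.zeros((n_q, n_traits))
    else:
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("monomorphic QTL: cannot scale effects to target covariance")
        # draw with the target correlation structure, then transform so that
        # sum_j 2 p_j (1-p_j) alpha_j alpha_j' == target_cov exactly
        base = rng.multivariate_normal(np.zeros(n_traits), target_cov, size=n_q)
        w = 2.0 * p * (1.0 - p)
        m = (base * w[:, None]).T @ base
        t = np.linalg.cholesky(target_cov) @ np.linalg.inv(np.linalg.cholesky(m))
        eff = base @ t.T
    if residual_var is None:
        residual_var = 1.0 - np.diag(target_cov) if np.any(target_cov) else np.ones(n_traits)
    return TraitArchitecture(
        effects=eff,
        base_genetic_cov=target_cov,
        residual_cov=np.diag(np.asarray(residual_var, dtype=float)),
        partition=partition,
    )


def true_genetic_values(pop: HaplotypePopulation, arch: TraitArchitecture) -> TraitValues:
    """TBV per animal per trait: dosage (0/1/2) at QTL times additive effects."""
    if arch.partition is None:
        raise ValueError("architecture carries no loci partition")
    dos = pop.dosage_matrix(arch.partition.qtl_idx)
    if dos.shape[1] != arch.effects.shape[0]:
        raise ValueError("QTL count mismatch between population and architecture")
    return TraitValues(tbv=dos @ arch.effects)


def tbv_from_dosages(qtl_dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """TBV from a precomputed QTL dosage matrix (scheduler fast path)."""
    return qtl_dosages @ arch.effects


def simulate_phenotypes(
    tv: TraitValues,
    arch: TraitArchitecture,
    schedule: np.ndarray,
    seed: int,
) -> TraitValues:
    """Add independent per-trait residuals; availability honors ``schedule``.

    ``schedule`` is an (n, n_traits) array of availability times (``inf`` for
    records never taken).  Phenotype values are drawn for every entry;
    whether a record enters an evaluation is governed by ``available_from``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    resid = rng.standard_normal(tv.tbv.shape) * np.sqrt(arch.residual_var)
    return TraitValues(
        tbv=tv.tbv,
        phenotypes=tv.tbv + resid,
        available_from=np.asarray(schedule, dtype=float),
    )


def trait_values_frame(tv: TraitValues, animal_ids, birth_time, sex):
    """Long-format table: animal_id, birth_time, sex, trait, value, is_tbv,
    available_from (one row per animal x trait x value kind)."""
    import pandas as pd

    rows = []
    ids = np.asarray(animal_ids)
    for t in range(tv.tbv.shape[1]):
        for kind, values in (("tbv", tv.tbv), ("phenotype", tv.phenotypes)):
            if values is None:
                continue
            avail = tv.available_from[:, t] if kind == "phenotype" and tv.available_from is not None else np.full(ids.size, np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": ids,
                        "birth_time": birth_time,
                        "sex": sex,
                        "trait": t + 1,
                        "value": values[:, t],
                        "is_tbv": kind == "tbv",
                        "available_from": avail,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def genic_variance(freqs, effects, index_weights=None):
    """Genic variance 2 sum_j p_j (1 - p_j) alpha_j^2 under no linkage.

    ``effects`` may be a TraitArchitecture or an (n_qtl, n_traits) array.
    Returns a per-trait vector, or a scalar when ``index_weights`` is given
    (effects collapsed to the index scale first).
    """
    if isinstance(effects, TraitArchitecture):
        effects = effects.effects
    p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    a = np.asarray(effects, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    w = 2.0 * p * (1.0 - p)
    if index_weights is not None:
        combined = a @ np.asarray(index_weights, dtype=float)
        return float(np.sum(w * combined**2))
    return w @ (a**2)
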