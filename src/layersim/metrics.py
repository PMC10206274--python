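"""Comparison metrics: normalization, conversion efficiency, inbreeding
rates, effective population size, generation interval.

Genetic values are reported in units of the genetic standard deviation of
the last burn-in year (year 10): that cohort is shifted to mean 0 and
scaled to SD 1, and genic SDs are scaled by the same factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inheritance import PedigreeTable

__all__ = [
    "normalize_to_burnin",
    "conversion_efficiency",
    "extrapolate",
    "inbreeding_from_heterozygosity",
    "rate_of_inbreeding",
    "delta_f_per_generation",
    "effective_population_size",
    "wright_ne",
    "generation_interval",
    "percentage_change",
]

GENIC_SD_COLUMNS = ("genic_sd_index", "genic_sd_t1", "genic_sd_t2", "genic_sd_t3")


def normalize_to_burnin(records: pd.DataFrame, ref_time: float = 10.0) -> pd.DataFrame:
    """Affine-normalize genetic values to the reference cohort.

    ``records`` must carry columns ``time``, ``mean_tbv``, ``sd_tbv`` and
    genic-SD columns.  The cohort at ``ref_time`` gets mean 0 / SD 1; all
    means are shifted and all SD-scale columns divided by its SD.
    """
    ref = records.loc[records["time"] == ref_time]
    if ref.empty:
        raise ValueError(f"no record at reference time {ref_time}")
    mu = float(ref["mean_tbv"].iloc[0])
    sd = float(ref["sd_tbv"].iloc[0])
    if sd <= 0:
        raise ValueError("zero genetic SD at the reference time")
    out = records.copy()
    out["gain"] = (out["mean_tbv"] - mu) / sd
    out["sd_tbv_norm"] = out["sd_tbv"] / sd
    for col in GENIC_SD_COLUMNS:
        if col in out.columns:
            out[col + "_norm"] = out[col] / sd
    return out


def conversion_efficiency(gain: np.ndarray, genic_sd: np.ndarray, ref_sd: float | None = None) -> float:
    """OLS slope of achieved gain on lost genic SD (intercept free).

    ``ref_sd`` defaults to the first element of ``genic_sd``; "lost" genic
    SD at time t is ``ref_sd - genic_sd[t]``.
    """
    gain = np.asarray(gain, float)
    genic_sd = np.asarray(genic_sd, float)
    if ref_sd is None:
        ref_sd = genic_sd[0]
    lost = ref_sd - genic_sd
    if gain.size < 2 or np.std(lost) == 0:
        raise ValueError("need at least two time points with distinct lost genic SD")
    slope = np.polyfit(lost, gain, 1)[0]
    return float(slope)


def extrapolate(slope: float, fraction_of_variance: float, ref_sd: float = 1.0) -> float:
    """Projected gain when a given fraction of genic variance is lost.

    A fraction v of variance lost corresponds to a lost genic SD of
    ``ref_sd * (1 - sqrt(1 - v))``; at v = 1 the whole genic SD is consumed.
    """
    if not 0.0 <= fraction_of_variance <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    lost_sd = ref_sd * (1.0 - np.sqrt(1.0 - fraction_of_variance))
    return float(slope * lost_sd)


def inbreeding_from_heterozygosity(het) -> np.ndarray:
    """F_t = 1 - Ho_t for a series of observed heterozygosities."""
    return 1.0 - np.asarray(het, float)


def rate_of_inbreeding(f_series: np.ndarray, times: np.ndarray | None = None) -> float:
    """dF per year: 1 - exp(beta), beta from regressing ln(1 - F_t) on t."""
    f = np.asarray(f_series, float)
    if np.any(f >= 1.0):
        raise ValueError("F = 1 in input: log(1 - F) undefined")
    if f.size < 2:
        raise ValueError("need at least two time points")
    t = np.arange(f.size, dtype=float) if times is None else np.asarray(times, float)
    beta = np.polyfit(t, np.log(1.0 - f), 1)[0]
    return float(1.0 - np.exp(beta))


def delta_f_per_generation(delta_f_year: float, generation_interval: float) -> float:
    """Compound the per-year rate over one generation of length L."""
    return float(1.0 - (1.0 - delta_f_year) ** generation_interval)


def effective_population_size(delta_f_year: float, generation_interval: float) -> float:
    """Ne = 1 / (2 L dF_year); nan (flagged missing) when dF <= 0."""
    if delta_f_year <= 0:
        return float("nan")
    return 1.0 / (2.0 * generation_interval * delta_f_year)


def wright_ne(n_males: float, n_females: float) -> float:
    """Ne = 4 Nm Nf / (Nm + Nf)."""
    if n_males <= 0 or n_females <= 0:
        raise ValueError("parent counts must be positive")
    return 4.0 * n_males * n_females / (n_males + n_females)


def generation_interval(ped: PedigreeTable, offspring_rows=None) -> float:
    """Mean parental age at offspring birth over both parents.

    Offspring with unknown parents are excluded (their count is available
    via the pedigree itself).
    """
    rows = np.arange(ped.n) if offspring_rows is None else np.asarray(offspring_rows, np.intp)
    ages = []
    for par in (ped.sire_id, ped.dam_id):
        p = par[rows]
        known = p > 0
        ages.append(ped.birth_time[rows[known]] - ped.birth_time[p[known] - 1])
    allages = np.concatenate(ages)
    if allages.size == 0:
        raise ValueError("no offspring with known parents")
    return float(allages.mean())


def percentage_change(new: float, base: float) -> float:
    """((new - base) / base) * 100."""
    if base == 0:
        raise ValueError("base value is zero")
    return (new - base) / base * 100.0
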