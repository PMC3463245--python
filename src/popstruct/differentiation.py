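"""Nei-family and standardized differentiation estimators.

Building blocks per locus, over k populations:

* ``hs`` — mean within-population gene diversity, mean_g(1 - sum_a p_ga^2)
* ``ht`` — total gene diversity 1 - sum_a pbar_a^2 from the *unweighted*
  mean frequency vector pbar across populations

When genotypes are available (diploid data) the Nei & Chesser small-sample
corrections are applied with nt the harmonic mean number of typed
individuals per population and Hobar the mean observed heterozygosity:

    Hs = nt/(nt - 1) * (hs - Hobar / (2 nt))
    Ht = ht + Hs / (nt k)

From corrected (or, for frequency-only input, uncorrected) Hs and Ht:

    Gst   = (Ht - Hs) / Ht
    G'st  = Gst (k - 1 + Hs) / ((k - 1)(1 - Hs))          (Hedrick)
    G''st = k (Ht - Hs) / ((k Ht - Hs)(1 - Hs))
    Dest  = (k/(k - 1)) (Ht - Hs) / (1 - Hs)              (Jost)

Multilocus values average Hs and Ht across loci first, then substitute the
means into each formula (the convention of the standardized-estimator
literature), rather than averaging per-locus ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlleleFreqTable,
    DataType,
    GenotypeDataset,
    ResamplingResult,
    ValidationError,
    allele_frequencies,
    permutation_pvalue,
)

__all__ = [
    "DifferentiationEstimates",
    "nei_chesser_hs_ht",
    "differentiation",
    "multilocus_stat",
    "pairwise_matrix",
    "resample",
    "PAIRWISE_STATISTICS",
]

STAT_NAMES = ("Gst", "Gprime_st", "Gpprime_st", "Dest")
PAIRWISE_STATISTICS = STAT_NAMES + ("Phi_pt", "Fprime_st", "sHua")


def _stats_from_hs_ht(hs: float, ht: float, k: int) -> dict[str, float]:
    if ht <= 0 or math.isnan(ht):
        return {s: math.nan for s in STAT_NAMES}
    gst = (ht - hs) / ht
    one_minus_hs = 1.0 - hs
    if one_minus_hs <= 0:
        gp = gpp = dest = math.nan
    else:
        gp = gst * (k - 1 + hs) / ((k - 1) * one_minus_hs)
        gpp = k * (ht - hs) / ((k * ht - hs) * one_minus_hs)
        dest = (k / (k - 1)) * (ht - hs) / one_minus_hs
    return dict(Gst=gst, Gprime_st=gp, Gpprime_st=gpp, Dest=dest)


def nei_chesser_hs_ht(
    table: AlleleFreqTable,
    locus: str,
    ho_mean: float | None = None,
    n_harmonic: float | None = None,
) -> tuple[float, float, int, bool]:
    """Within/total gene diversity (Hs, Ht) at one locus.

    Returns (Hs, Ht, k, corrected).  ``corrected`` is False for
    frequency-only input (no genotypes behind the table) or haploid data,
    where the uncorrected forms are used; in that case ``ho_mean`` and
    ``n_harmonic`` are ignored.
    """
    pops = [p for p in table.pops if (locus, p) in table.freqs]
    k = len(pops)
    if k < 2:
        raise ValidationError(f"locus {locus!r}: fewer than 2 populations typed")
    alleles = table.alleles_at(locus)
    vecs = np.array([table.freq_vector(locus, p, alleles) for p in pops])
    hs_unc = float(np.mean(1.0 - np.sum(vecs**2, axis=1)))
    pbar = vecs.mean(axis=0)  # unweighted across populations
    ht_unc = float(1.0 - np.sum(pbar**2))
    corrected = (
        table.from_genotypes
        and table.ploidy == 2
        and ho_mean is not None
        and n_harmonic is not None
        and n_harmonic > 1
    )
    if not corrected:
        return hs_unc, ht_unc, k, False
    nt = n_harmonic
    hs = nt / (nt - 1.0) * (hs_unc - ho_mean / (2.0 * nt))
    ht = ht_unc + hs / (nt * k)
    return hs, ht, k, True


@dataclass
class DifferentiationEstimates:
    per_locus: pd.DataFrame  # locus, Hs, Ht, k, n_harmonic, Gst, ..., Dest
    multilocus: dict[str, float]
    k: int
    corrected: bool

    def __getitem__(self, stat: str) -> float:
        return self.multilocus[stat]


def _locus_ho_and_n(ds: GenotypeDataset, l: int) -> tuple[float, float]:
    """Mean observed heterozygosity and harmonic-mean typed N across pops."""
    cols = ds.locus_columns(l)
    hos, ns = [], []
    for pop in ds.pop_names:
        sub = cols[ds.pop_indices(pop)]
        typed = sub[(sub != ds.missing_code).all(axis=1)]
        if typed.shape[0] == 0:
            continue
        ns.append(typed.shape[0])
        if ds.ploidy == 2:
            hos.append(float(np.mean(typed[:, 0] != typed[:, 1])))
    ho = float(np.mean(hos)) if hos else math.nan
    n_h = len(ns) / np.sum(1.0 / np.asarray(ns, dtype=float)) if ns else math.nan
    return ho, float(n_h)


def differentiation(
    data: GenotypeDataset | AlleleFreqTable,
) -> DifferentiationEstimates:
    """Per-locus and multilocus differentiation estimates.

    Accepts either a genotype dataset (sample-size-corrected Hs/Ht) or a
    published allele-frequency table (uncorrected, flagged).  Loci that are
    monomorphic overall (Ht = 0) are excluded from the multilocus averages
    with a warning.
    """
    if isinstance(data, GenotypeDataset):
        ds: GenotypeDataset | None = data
        table = allele_frequencies(data)
    else:
        ds, table = None, data
    k_pops = len(table.pops)
    if k_pops < 2:
        raise ValidationError("differentiation requires at least 2 populations")
    rows = []
    for li, locus in enumerate(table.loci):
        typed_pops = [p for p in table.pops if (locus, p) in table.freqs]
        if len(typed_pops) < len(table.pops):
            warnings.warn(f"locus {locus!r} untyped in some populations; skipped")
            continue
        ho = n_h = None
        if ds is not None and ds.ploidy == 2:
            ho, n_h = _locus_ho_and_n(ds, li)
        hs, ht, k, corrected = nei_chesser_hs_ht(table, locus, ho, n_h)
        row = dict(locus=locus, Hs=hs, Ht=ht, k=k, n_harmonic=n_h)
        row.update(_stats_from_hs_ht(hs, ht, k))
        rows.append(row)
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        raise ValidationError("no locus typed in all populations")
    usable = per_locus[per_locus.Ht > 0]
    if usable.empty:
        warnings.warn("all loci monomorphic overall; statistics undefined")
        multilocus = {s: math.nan for s in STAT_NAMES} | dict(Hs=math.nan, Ht=math.nan)
    else:
        if len(usable) < len(per_locus):
            warnings.warn("monomorphic loci excluded from multilocus averages")
        hs_bar = float(usable.Hs.mean())
        ht_bar = float(usable.Ht.mean())
        multilocus = dict(Hs=hs_bar, Ht=ht_bar)
        multilocus.update(_stats_from_hs_ht(hs_bar, ht_bar, k_pops))
    corrected = bool(rows and table.from_genotypes and table.ploidy == 2)
    return DifferentiationEstimates(per_locus, multilocus, k_pops, corrected)


def multilocus_stat(data: GenotypeDataset | AlleleFreqTable, stat: str) -> float:
    """Convenience scalar accessor (also usable as a resampling target)."""
    if stat in STAT_NAMES or stat in ("Hs", "Ht"):
        return differentiation(data)[stat]
    if stat == "Phi_pt":
        from . import amova
        from .distance import genotype_distance

        assert isinstance(data, GenotypeDataset)
        return amova.amova_two_level(genotype_distance(data), data.pops).phi["Phi_pt"]
    if stat == "Fprime_st":
        from . import amova

        assert isinstance(data, GenotypeDataset)
        return amova.f_prime_st(data).f_prime_st
    if stat == "sHua":
        from .shannon import shannon_partition

        return shannon_partition(data).multilocus["I_pop_total"]
    raise ValidationError(f"unknown statistic {stat!r}")


def _pop_pair_subset(data, pop_i: str, pop_j: str):
    if isinstance(data, GenotypeDataset):
        idx = np.concatenate([data.pop_indices(pop_i), data.pop_indices(pop_j)])
        return data.subset(idx, keep_regions=False)
    return AlleleFreqTable(
        loci=list(data.loci),
        pops=[pop_i, pop_j],
        freqs={k: v for k, v in data.freqs.items() if k[1] in (pop_i, pop_j)},
        n_typed={k: v for k, v in data.n_typed.items() if k[1] in (pop_i, pop_j)},
        from_genotypes=data.from_genotypes,
        ploidy=data.ploidy,
    )


def pairwise_matrix(
    data: GenotypeDataset | AlleleFreqTable, stat: str
) -> pd.DataFrame:
    """Symmetric population x population matrix of a two-population statistic.

    Every cell is computed on the two-population subset, so k = 2 in all
    formulas.  Frequency-only tables (uncorrected mode, where the
    identical-populations = 0 identity is exact) support the Gst-family
    statistics; distance-based Phi_pt / Fprime_st and sHua need genotypes.
    Undefined cells (e.g. a monomorphic pair) are NaN.
    """
    if stat not in PAIRWISE_STATISTICS:
        raise ValidationError(f"statistic must be one of {PAIRWISE_STATISTICS}")
    if isinstance(data, AlleleFreqTable) and stat in ("Phi_pt", "Fprime_st"):
        raise ValidationError(f"{stat} requires genotype data")
    pops = data.pop_names if isinstance(data, GenotypeDataset) else list(data.pops)
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = _pop_pair_subset(data, pops[i], pops[j])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    val = multilocus_stat(sub, stat)
                except ValidationError:
                    val = math.nan
            m[i, j] = m[j, i] = val
    return pd.DataFrame(m, index=pops, columns=pops)


def resample(
    ds: GenotypeDataset,
    stat: str | object,
    mode: str,
    n_resamples: int,
    seed: int,
) -> ResamplingResult:
    """Permutation test / jackknife SE / bootstrap CI for a multilocus statistic.

    * ``permutation`` shuffles individuals among populations (genotypes move
      as intact units, population sizes preserved); one-tailed p = (b+1)/(m+1).
    * ``jackknife_loci`` deletes one locus at a time;
      SE = sqrt(((L-1)/L) sum (theta_(-l) - mean)^2).
    * ``bootstrap_loci`` resamples loci with replacement; 95% percentile CI.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    stat_fn = (lambda d: multilocus_stat(d, stat)) if isinstance(stat, str) else stat
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = float(stat_fn(ds))
        if mode == "permutation":
            null = np.empty(n_resamples)
            labels = np.asarray(ds.pops, dtype=object)
            for b in range(n_resamples):
                null[b] = stat_fn(ds.with_pops(list(rng.permutation(labels))))
            return ResamplingResult(
                observed, mode, null,
                p_value=permutation_pvalue(observed, null),
                n_resamples=n_resamples, seed=seed,
            )
        if mode == "jackknife_loci":
            L = ds.n_loci
            if L < 2:
                raise ValidationError("jackknife over loci needs at least 2 loci")
            reps = np.array([
                stat_fn(ds.subset_loci([l for l in range(L) if l != drop]))
                for drop in range(L)
            ])
            se = math.sqrt((L - 1) / L * np.sum((reps - reps.mean()) ** 2))
            return ResamplingResult(observed, mode, reps, se=se,
                                    n_resamples=L, seed=seed)
        if mode == "bootstrap_loci":
            L = ds.n_loci
            if L < 2:
                raise ValidationError("bootstrap over loci needs at least 2 loci")
            reps = np.array([
                stat_fn(ds.subset_loci(rng.integers(0, L, size=L)))
                for _ in range(n_resamples)
            ])
            lo, hi = np.percentile(reps[~np.isnan(reps)], [2.5, 97.5])
            return ResamplingResult(observed, mode, reps,
                                    ci_low=float(lo), ci_high=float(hi),
                                    n_resamples=n_resamples, seed=seed)
    raise ValidationError(f"unknown resampling mode {mode!r}")
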