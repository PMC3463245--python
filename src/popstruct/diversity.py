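"""Per-locus, per-population diversity summaries and Hardy-Weinberg tests.

For each locus within each population with N typed individuals and allele
frequencies p_i:

* ``Na`` — number of observed alleles
* ``Ne`` — effective alleles, 1 / sum(p_i^2)
* ``I``  — Shannon information index, -sum(p_i ln p_i) (nats)
* ``Ho`` — observed heterozygote proportion (diploid only)
* ``He`` — expected heterozygosity, 1 - sum(p_i^2)
* ``uHe`` — unbiased expected heterozygosity, (2N / (2N - 1)) He
* ``F``  — fixation index, 1 - Ho / He, undefined when He = 0

The HWE test is the classical chi-square on genotype counts with
df = k(k-1)/2 for k observed alleles; cells with zero expectation are
skipped and a small-sample caution is raised when any expected count < 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataType, GenotypeDataset, ValidationError, allele_frequencies

__all__ = ["diversity_summary", "hwe_chi2", "DiversitySummary", "HweTestResult"]


@dataclass
class DiversitySummary:
    table: pd.DataFrame  # columns: locus, pop, N, Na, Ne, I, Ho, He, uHe, F

    def cell(self, locus: str, pop: str) -> pd.Series:
        t = self.table
        row = t[(t["locus"] == locus) & (t["pop"] == pop)]
        return row.iloc[0]

    def to_long(self) -> pd.DataFrame:
        return self.table.melt(
            id_vars=["locus", "pop"], var_name="statistic", value_name="value"
        )


@dataclass
class HweTestResult:
    table: pd.DataFrame  # locus, pop, chi2, df, p_value, caution, reason
    expected_counts: dict[tuple[str, str], dict[tuple[int, int], float]] = field(
        default_factory=dict
    )

    def cell(self, locus: str, pop: str) -> pd.Series:
        t = self.table
        return t[(t["locus"] == locus) & (t["pop"] == pop)].iloc[0]


def diversity_summary(ds: GenotypeDataset) -> DiversitySummary:
    """Diversity statistics per (locus, population).

    Ho, uHe and F are reported only for diploid data; monomorphic loci get
    F = NaN (undefined, never coerced to 0).
    """
    if ds.data_type is DataType.BINARY:
        raise ValidationError("diversity summary requires codominant or haploid data")
    diploid = ds.data_type is DataType.CODOMINANT_DIPLOID
    freqs = allele_frequencies(ds)
    rows = []
    for locus in ds.locus_names:
        l = ds.locus_names.index(locus)
        cols = ds.locus_columns(l)
        for pop in ds.pop_names:
            cell = freqs.freqs.get((locus, pop))
            if cell is None:
                continue
            p = np.array(list(cell.values()))
            sum_p2 = float(np.sum(p * p))
            na = len(cell)
            ne = 1.0 / sum_p2
            shannon = float(-np.sum(p * np.log(p)))
            he = 1.0 - sum_p2
            idx = ds.pop_indices(pop)
            sub = cols[idx]
            typed = sub[(sub != ds.missing_code).all(axis=1)]
            n = typed.shape[0]
            ho = uhe = f = math.nan
            if diploid and n > 0:
                ho = float(np.mean(typed[:, 0] != typed[:, 1]))
                uhe = he * (2 * n) / (2 * n - 1) if n > 0 else math.nan
                f = 1.0 - ho / he if he > 0 else math.nan
            rows.append(
                dict(locus=locus, pop=pop, N=n, Na=na, Ne=ne, I=shannon,
                     Ho=ho, He=he, uHe=uhe, F=f)
            )
    return DiversitySummary(pd.DataFrame(rows))


def hwe_chi2(ds: GenotypeDataset) -> HweTestResult:
    """Chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Expected counts are N p_i^2 for homozygotes and 2 N p_i p_j for
    heterozygotes.  Monomorphic (locus, pop) cells are skipped with reason
    ``"monomorphic"``.
    """
    if ds.data_type is not DataType.CODOMINANT_DIPLOID:
        raise ValidationError("HWE test requires codominant diploid data")
    rows = []
    expected_all: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for l, locus in enumerate(ds.locus_names):
        cols = ds.locus_columns(l)
        for pop in ds.pop_names:
            sub = cols[ds.pop_indices(pop)]
            typed = sub[(sub != 0).all(axis=1)]
            n = typed.shape[0]
            if n == 0:
                continue
            alleles, counts = np.unique(typed, return_counts=True)
            k = len(alleles)
            if k < 2:
                rows.append(dict(locus=locus, pop=pop, chi2=math.nan, df=0,
                                 p_value=math.nan, caution=False,
                                 reason="monomorphic"))
                continue
            p = counts / counts.sum()
            pmap = dict(zip(alleles.tolist(), p.tolist()))
            obs: dict[tuple[int, int], int] = {}
            for a, b in typed:
                key = (int(min(a, b)), int(max(a, b)))
                obs[key] = obs.get(key, 0) + 1
            exp: dict[tuple[int, int], float] = {}
            for i, a in enumerate(alleles.tolist()):
                for b in alleles.tolist()[i:]:
                    if a == b:
                        exp[(a, b)] = n * pmap[a] ** 2
                    else:
                        exp[(a, b)] = 2 * n * pmap[a] * pmap[b]
            chi2 = sum(
                (obs.get(g, 0) - e) ** 2 / e for g, e in exp.items() if e > 0
            )
            df = k * (k - 1) // 2
            pval = float(stats.chi2.sf(chi2, df))
            caution = any(e < 5 for e in exp.values())
            expected_all[(locus, pop)] = exp
            rows.append(dict(locus=locus, pop=pop, chi2=float(chi2), df=df,
                             p_value=pval, caution=caution, reason=""))
    return HweTestResult(pd.DataFrame(rows), expected_all)
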