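"""Pairwise linkage disequilibrium for biallelic loci.

With haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) and allele margins
p_A = p_AB + p_Ab, p_B = p_AB + p_aB:

    D  = p_AB - p_A p_B
    D' = D / D_max,  D_max = min(p_A p_b, p_a p_B) if D > 0
                           else min(p_A p_B, p_a p_b)
    r  = D / sqrt(p_A p_a p_B p_b),   r2 = r^2
    chi2 = n_units * r2  (df = 1; n_units = counted haplotypes when phase is
    known, 2N gene copies under the EM estimator)

When phase is unknown the only ambiguous genotype is the double
heterozygote AaBb, which may be AB/ab or Ab/aB.  The EM algorithm splits
its count between the two phases in proportion to p_AB p_ab vs p_Ab p_aB
(E-step), re-estimates haplotype frequencies from the expected counts
(M-step), and iterates from linkage-equilibrium starting values until the
largest frequency change is below 1e-10.  The observed-data log-likelihood
is non-decreasing at every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataType, GenotypeDataset, ValidationError

__all__ = ["LDResult", "ld_phase_known", "ld_phase_unknown_em", "ld_all_pairs"]

HAPLOTYPES = ("AB", "Ab", "aB", "ab")


@dataclass
class LDResult:
    mode: str                      # phase_known | phase_unknown_ml
    hap_freqs: tuple[float, float, float, float]
    D: float
    D_prime: float
    r: float
    r2: float
    chi2: float
    p_value: float
    n_units: int
    defined: bool = True
    reason: str = ""
    em_iterations: int = 0
    em_converged: bool = True
    loglik_path: tuple[float, ...] = ()
    pair: tuple[str, str] | None = None


def _measures(h: np.ndarray, n_units: int, mode: str, **extra) -> LDResult:
    pAB, pAb, paB, pab = (float(x) for x in h)
    pA, pa = pAB + pAb, paB + pab
    pB, pb = pAB + paB, pAb + pab
    if min(pA, pa, pB, pb) <= 0:
        return LDResult(mode, (pAB, pAb, paB, pab), math.nan, math.nan, math.nan,
                        math.nan, math.nan, math.nan, n_units, defined=False,
                        reason="monomorphic margin", **extra)
    D = pAB - pA * pB
    dmax = min(pA * pb, pa * pB) if D > 0 else min(pA * pB, pa * pb)
    dprime = D / dmax if dmax > 0 else 0.0
    r = D / math.sqrt(pA * pa * pB * pb)
    chi2 = n_units * r * r
    return LDResult(mode, (pAB, pAb, paB, pab), D, dprime, r, r * r, chi2,
                    float(stats.chi2.sf(chi2, 1)), n_units, **extra)


def ld_phase_known(hap_counts) -> LDResult:
    """LD measures from observed haplotype counts (AB, Ab, aB, ab)."""
    c = np.asarray(hap_counts, dtype=float)
    if c.shape != (4,) or (c < 0).any():
        raise ValidationError("hap_counts must be 4 non-negative numbers")
    n = c.sum()
    if n < 1:
        raise ValidationError("at least one haplotype required")
    return _measures(c / n, int(n), "phase_known")


def _em_loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Observed-data log-likelihood of the 3x3 genotype table."""
    pAB, pAb, paB, pab = h
    # genotype probability = sum over compatible phased pairs
    probs = np.empty((3, 3))
    gh = {0: ("A", "A"), 1: ("A", "a"), 2: ("a", "a")}
    hp = {"AB": pAB, "Ab": pAb, "aB": paB, "ab": pab}
    for i in range(3):
        for j in range(3):
            a1, a2 = gh[i]
            b1, b2 = {0: ("B", "B"), 1: ("B", "b"), 2: ("b", "b")}[j]
            p = hp[a1 + b1] * hp[a2 + b2]
            if (a1, b1) != (a2, b2):
                p += hp[a1 + b2] * hp[a2 + b1]
            probs[i, j] = p
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(np.sum(counts * lp))


def ld_phase_unknown_em(
    geno_counts, tol: float = 1e-10, max_iter: int = 1000
) -> LDResult:
    """Maximum-likelihood LD from a 3x3 two-locus diploid genotype table.

    ``geno_counts[i, j]`` counts individuals with i copies of allele a at
    the first locus and j copies of allele b at the second (0 = AA/BB row
    and column first).
    """
    counts = np.asarray(geno_counts, dtype=float)
    if counts.shape != (3, 3) or (counts < 0).any():
        raise ValidationError("geno_counts must be a non-negative 3x3 table")
    N = counts.sum()
    if N < 1:
        raise ValidationError("at least one individual required")
    # allele counts (copies of A and B among 2N gene copies)
    nA = 2 * counts[0].sum() + counts[1].sum()
    nB = 2 * counts[:, 0].sum() + counts[:, 1].sum()
    pA, pB = nA / (2 * N), nB / (2 * N)
    if min(pA, 1 - pA, pB, 1 - pB) <= 0:
        return _measures(np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                                   (1 - pA) * (1 - pB)]),
                         int(2 * N), "phase_unknown_ml")
    # unambiguous haplotype counts contributed by the 8 phase-certain cells
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): (2, 0, 0, 0), (0, 1): (1, 1, 0, 0), (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0), (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0), (2, 1): (0, 0, 1, 1), (2, 2): (0, 0, 0, 2),
    }
    for (i, j), w in contrib.items():
        base += counts[i, j] * np.asarray(w, dtype=float)
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    loglik_path = [_em_loglik(counts, h)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = h[0] * h[3] + h[1] * h[2]
        frac_cis = 0.5 if denom == 0 else h[0] * h[3] / denom
        expected = base + n_dh * np.array(
            [frac_cis, 1 - frac_cis, 1 - frac_cis, frac_cis]
        )
        h_new = expected / (2 * N)
        loglik_path.append(_em_loglik(counts, h_new))
        delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < tol:
            converged = True
            break
    return _measures(h, int(2 * N), "phase_unknown_ml",
                     em_iterations=it, em_converged=converged,
                     loglik_path=tuple(loglik_path))


def genotype_table(ds: GenotypeDataset, l1: int, l2: int) -> np.ndarray:
    """3x3 two-locus genotype count table for a pair of biallelic loci.

    Allele "A"/"B" is the numerically smaller code at each locus.
    """
    g1, g2 = ds.locus_columns(l1), ds.locus_columns(l2)
    typed = (g1 != 0).all(axis=1) & (g2 != 0).all(axis=1)
    g1, g2 = g1[typed], g2[typed]

    def dosage(g: np.ndarray) -> np.ndarray:
        ref = int(np.min(g[g > 0]))
        return (g != ref).sum(axis=1)

    counts = np.zeros((3, 3))
    for i, j in zip(dosage(g1), dosage(g2)):
        counts[i, j] += 1
    return counts


def ld_all_pairs(
    ds: GenotypeDataset, phase_known: bool = False, bonferroni: bool = False
) -> pd.DataFrame:
    """LD for every unordered pair of biallelic loci in a diploid dataset.

    ``phase_known=True`` treats each individual's two allele columns as
    phased haplotypes; the default uses the EM estimator on the collapsed
    genotype table.
    """
    if ds.data_type is not DataType.CODOMINANT_DIPLOID:
        raise ValidationError("LD scan requires codominant diploid data")
    bad = [l.name for l in ds.loci if len(l.observed_alleles) > 2]
    if bad:
        raise ValidationError(f"non-biallelic loci: {bad}")
    if ds.n_loci < 2:
        raise ValidationError("need at least 2 biallelic loci")
    rows = []
    n_pairs = ds.n_loci * (ds.n_loci - 1) // 2
    for l1, l2 in combinations(range(ds.n_loci), 2):
        if phase_known:
            g1, g2 = ds.locus_columns(l1), ds.locus_columns(l2)
            typed = (g1 != 0).all(axis=1) & (g2 != 0).all(axis=1)
            g1, g2 = g1[typed], g2[typed]
            ref1, ref2 = int(np.min(g1)), int(np.min(g2))
            counts = np.zeros(4)
            for copy in range(2):
                a = g1[:, copy] == ref1
                b = g2[:, copy] == ref2
                counts[0] += np.sum(a & b)
                counts[1] += np.sum(a & ~b)
                counts[2] += np.sum(~a & b)
                counts[3] += np.sum(~a & ~b)
            res = ld_phase_known(counts)
        else:
            res = ld_phase_unknown_em(genotype_table(ds, l1, l2))
        row = dict(
            locusA=ds.locus_names[l1], locusB=ds.locus_names[l2], mode=res.mode,
            D=res.D, D_prime=res.D_prime, r=res.r, r2=res.r2,
            chi2=res.chi2, p_value=res.p_value, defined=res.defined,
        )
        if bonferroni:
            row["p_bonferroni"] = (
                min(1.0, res.p_value * n_pairs) if res.defined else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
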