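"""Distance-based analysis of molecular variance (AMOVA).

Sums of squares are computed directly from the individual squared-distance
matrix: the total SS is (1/N) sum_{i<j} d2_ij and the within-group SS for a
group g of size n_g is (1/n_g) sum_{i<j in g} d2_ij.  Variance components
follow the standard (unequal-size) nested ANOVA expectations, and the
Phi-statistics are ratios of variance components:

    two-level:   Phi_pt = s2_among / (s2_among + s2_within)
    three-level: Phi_rt = s2_R / tot,  Phi_pr = s2_P / (s2_P + s2_W),
                 Phi_pt = (s2_R + s2_P) / tot

Negative variance components are retained in the table; a Phi whose
denominator is <= 0 is flagged undefined (NaN) rather than clamped.

Standardized F'st divides the observed Phi_pt by the maximum attainable
under the observed within-population structure, obtained by recoding
alleles so no allele is shared between populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    GenotypeDataset,
    ResamplingResult,
    ValidationError,
    permutation_pvalue,
)
from .distance import genotype_distance

__all__ = [
    "AmovaResult",
    "amova_two_level",
    "amova_three_level",
    "permute_amova",
    "f_prime_st",
    "FPrimeStResult",
]


@dataclass
class AmovaResult:
    table: pd.DataFrame            # stratum, df, SS, MS
    components: dict[str, float]   # sigma2 per stratum
    phi: dict[str, float]
    n0: dict[str, float] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)


def _group_ss(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def _labels_to_groups(labels) -> dict[str, np.ndarray]:
    labels = list(labels)
    out: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        out.setdefault(g, []).append(i)
    return {g: np.asarray(ix) for g, ix in out.items()}


def amova_two_level(d2: DistanceMatrix | np.ndarray, pops) -> AmovaResult:
    """Among/within-population AMOVA on an individual distance matrix."""
    m = d2.d2 if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    n = m.shape[0]
    groups = _labels_to_groups(pops)
    k = len(groups)
    if k < 2:
        raise ValidationError("AMOVA requires at least 2 populations")
    sizes = np.array([len(ix) for ix in groups.values()], dtype=float)
    if (sizes == 0).any():
        raise ValidationError("population with 0 samples")
    ss_total = m[np.triu_indices(n, 1)].sum() / n
    ss_within = _group_ss(m, list(groups.values()))
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else math.nan
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    s2_w = ms_within
    s2_a = (ms_among - ms_within) / n0
    tot = s2_a + s2_w
    undefined: list[str] = []
    if tot <= 0:
        phi_pt = 0.0 if ss_total == 0 else math.nan
        if ss_total != 0:
            undefined.append("Phi_pt")
    else:
        phi_pt = s2_a / tot
    table = pd.DataFrame(
        dict(
            stratum=["among_pops", "within_pops", "total"],
            df=[df_among, df_within, n - 1],
            SS=[ss_among, ss_within, ss_total],
            MS=[ms_among, ms_within, math.nan],
        )
    )
    return AmovaResult(
        table,
        components={"among_pops": s2_a, "within_pops": s2_w},
        phi={"Phi_pt": phi_pt},
        n0={"n0": float(n0)},
        undefined=undefined,
    )


def amova_three_level(
    d2: DistanceMatrix | np.ndarray, pops, regions: dict[str, str]
) -> AmovaResult:
    """Nested AMOVA: regions / populations within regions / within populations."""
    m = d2.d2 if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    n = m.shape[0]
    pops = list(pops)
    pop_groups = _labels_to_groups(pops)
    region_labels = [regions[p] for p in pops]
    region_groups = _labels_to_groups(region_labels)
    k, a = len(pop_groups), len(region_groups)
    if a < 2:
        raise ValidationError("3-level AMOVA requires at least 2 regions")
    if k == a:
        raise ValidationError("Phi_pr undefined: every region holds a single population")

    ss_total = m[np.triu_indices(n, 1)].sum() / n
    ss_wp = _group_ss(m, list(pop_groups.values()))
    ss_wr = _group_ss(m, list(region_groups.values()))
    ss_ap = ss_wr - ss_wp          # among pops within regions
    ss_ar = ss_total - ss_wr       # among regions
    df_ar, df_ap, df_wp = a - 1, k - a, n - k

    pop_sizes = {g: len(ix) for g, ix in pop_groups.items()}
    region_of_pop: dict[str, str] = {}
    for p, ix in pop_groups.items():
        region_of_pop[p] = region_labels[ix[0]]
    region_sizes = {r: len(ix) for r, ix in region_groups.items()}
    # unequal-size coefficients of the nested ANOVA expectations
    sum_sq_within_region = sum(
        sum(pop_sizes[p] ** 2 for p in pop_groups if region_of_pop[p] == r)
        / region_sizes[r]
        for r in region_groups
    )
    sum_sq_over_n = sum(s**2 for s in pop_sizes.values()) / n
    n1 = (n - sum_sq_within_region) / df_ap
    n2 = (sum_sq_within_region - sum_sq_over_n) / df_ar
    n3 = (n - sum(s**2 for s in region_sizes.values()) / n) / df_ar

    ms_ar, ms_ap = ss_ar / df_ar, ss_ap / df_ap
    ms_wp = ss_wp / df_wp if df_wp > 0 else math.nan
    s2_w = ms_wp
    s2_p = (ms_ap - s2_w) / n1
    s2_r = (ms_ar - s2_w - n2 * s2_p) / n3

    tot = s2_r + s2_p + s2_w
    undefined: list[str] = []
    phi: dict[str, float] = {}
    if tot <= 0:
        if ss_total == 0:
            phi = {"Phi_rt": 0.0, "Phi_pr": 0.0, "Phi_pt": 0.0}
        else:
            phi = {s: math.nan for s in ("Phi_rt", "Phi_pr", "Phi_pt")}
            undefined += list(phi)
    else:
        phi["Phi_rt"] = s2_r / tot
        phi["Phi_pt"] = (s2_r + s2_p) / tot
        pw = s2_p + s2_w
        if pw <= 0:
            # no variation below the region stratum at all is a true zero;
            # a negative-component denominator is undefined, not clamped
            if abs(ss_ap) < 1e-12 and abs(ss_wp) < 1e-12:
                phi["Phi_pr"] = 0.0
            else:
                phi["Phi_pr"] = math.nan
                undefined.append("Phi_pr")
        else:
            phi["Phi_pr"] = s2_p / pw
    table = pd.DataFrame(
        dict(
            stratum=["among_regions", "among_pops_within_regions", "within_pops", "total"],
            df=[df_ar, df_ap, df_wp, n - 1],
            SS=[ss_ar, ss_ap, ss_wp, ss_total],
            MS=[ms_ar, ms_ap, ms_wp, math.nan],
        )
    )
    return AmovaResult(
        table,
        components={
            "among_regions": s2_r,
            "among_pops_within_regions": s2_p,
            "within_pops": s2_w,
        },
        phi=phi,
        n0={"n1": n1, "n2": n2, "n3": n3},
        undefined=undefined,
    )


def permute_amova(
    d2: DistanceMatrix | np.ndarray,
    pops,
    which_phi: str = "Phi_pt",
    regions: dict[str, str] | None = None,
    m: int = 999,
    seed: int | None = None,
) -> ResamplingResult:
    """Permutation test for a Phi-statistic, one-tailed greater.

    Exchangeable units: individuals among populations for Phi_pt; individuals
    among populations within their region for Phi_pr; whole populations
    among regions for Phi_rt.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    mat = d2.d2 if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    pops = list(pops)
    rng = np.random.default_rng(seed)

    def observed_phi(pop_labels, region_map):
        if regions is None:
            return amova_two_level(mat, pop_labels).phi["Phi_pt"]
        return amova_three_level(mat, pop_labels, region_map).phi[which_phi]

    obs = observed_phi(pops, regions)
    null = np.empty(m)
    pop_arr = np.asarray(pops, dtype=object)
    if which_phi == "Phi_rt":
        assert regions is not None
        pop_names = list(dict.fromkeys(pops))
        region_values = [regions[p] for p in pop_names]
        for b in range(m):
            shuffled = rng.permutation(np.asarray(region_values, dtype=object))
            rmap = dict(zip(pop_names, shuffled))
            null[b] = observed_phi(pops, rmap)
    elif which_phi == "Phi_pr":
        assert regions is not None
        region_arr = np.asarray([regions[p] for p in pops], dtype=object)
        for b in range(m):
            labels = pop_arr.copy()
            for r in np.unique(region_arr):
                ix = np.flatnonzero(region_arr == r)
                labels[ix] = labels[ix[rng.permutation(ix.size)]]
            null[b] = observed_phi(list(labels), regions)
    else:  # Phi_pt: individuals among populations
        for b in range(m):
            null[b] = observed_phi(list(rng.permutation(pop_arr)), regions)
    return ResamplingResult(
        obs, "permutation", null,
        p_value=permutation_pvalue(obs, null), n_resamples=m, seed=seed,
    )


@dataclass
class FPrimeStResult:
    phi_pt: float
    phi_pt_max: float
    f_prime_st: float
    reason: str = ""


def maximal_recode(ds: GenotypeDataset) -> GenotypeDataset:
    """Recode alleles so no allele is shared between populations.

    Population g's allele a maps to a + g * (max_allele + 1): deterministic,
    reversible, and preserving the within-population genotype structure.
    """
    shift = int(ds.alleles.max(initial=0)) + 1
    new = ds.alleles.copy()
    for g, pop in enumerate(ds.pop_names):
        idx = ds.pop_indices(pop)
        block = new[idx]
        block[block != ds.missing_code] += g * shift
        new[idx] = block
    out = ds.subset(np.arange(ds.n_samples))
    out.alleles = new
    return out.validate()


def f_prime_st(ds: GenotypeDataset) -> FPrimeStResult:
    """Standardized F'st = Phi_pt / Phi_pt(max) from recoded data."""
    d2 = genotype_distance(ds)
    phi = amova_two_level(d2, ds.pops).phi["Phi_pt"]
    d2_max = genotype_distance(maximal_recode(ds))
    phi_max = amova_two_level(d2_max, ds.pops).phi["Phi_pt"]
    if not (phi_max > 0):
        return FPrimeStResult(phi, phi_max, math.nan, reason="Phi_pt_max <= 0")
    return FPrimeStResult(phi, phi_max, phi / phi_max)
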