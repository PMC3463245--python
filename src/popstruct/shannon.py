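"""Shannon information partitioning of allelic diversity.

For one locus, let q_g be the allele distribution of population g and
w_g its weight (its number of typed gene copies).  With H(q) = -sum q ln q:

* ``sHt`` — entropy of the pooled (weighted mixture) allele distribution
* ``sHs`` — weighted mean within-population entropy, sum_g w_g H(q_g) / sum w
* ``sHr`` — weighted mean within-region pooled entropy (3-level designs)

The mutual information between allele identity and population identity is
``sHua = sHt - sHs`` (written I_pop_total here); with regions the partition
is exactly additive:

    I_pop_total = I_region_total + I_pop_region
                = (sHt - sHr)   + (sHr - sHs)

All indices are in nats; the identities are base-invariant.  Multilocus
values are unweighted means of per-locus indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AlleleFreqTable,
    GenotypeDataset,
    ResamplingResult,
    ValidationError,
    allele_frequencies,
    permutation_pvalue,
)

__all__ = ["ShannonPartition", "shannon_partition", "permute_shannon"]


def _entropy(q: np.ndarray) -> float:
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)))


@dataclass
class ShannonPartition:
    per_locus: pd.DataFrame
    multilocus: dict[str, float]
    levels: int

    def __getitem__(self, key: str) -> float:
        return self.multilocus[key]


def shannon_partition(
    data: GenotypeDataset | AlleleFreqTable,
    levels: int = 2,
    regions: dict[str, str] | None = None,
) -> ShannonPartition:
    """Two- or three-level Shannon diversity partition.

    Weights are typed gene copies per (locus, population); loci with a
    stratum holding zero typed copies are skipped with a warning.
    """
    if isinstance(data, GenotypeDataset):
        table = allele_frequencies(data)
        if regions is None:
            regions = data.regions
    else:
        table = data
    if levels == 3 and regions is None:
        raise ValidationError("3-level partition requires a region map")
    if len(table.pops) < 1:
        raise ValidationError("partition requires at least 1 population")
    rows = []
    for locus in table.loci:
        pops = [p for p in table.pops if (locus, p) in table.freqs]
        if len(pops) < len(table.pops):
            warnings.warn(f"locus {locus!r} lacks typed copies in some stratum; skipped")
            continue
        alleles = table.alleles_at(locus)
        vecs = {p: table.freq_vector(locus, p, alleles) for p in pops}
        w = np.array([table.n_typed[(locus, p)] for p in pops], dtype=float)
        w /= w.sum()
        pooled = np.sum([wi * vecs[p] for wi, p in zip(w, pops)], axis=0)
        sht = _entropy(pooled)
        shs = float(np.sum([wi * _entropy(vecs[p]) for wi, p in zip(w, pops)]))
        row = dict(locus=locus, sHt=sht, sHs=shs, I_pop_total=sht - shs)
        if levels == 3:
            assert regions is not None
            shr = 0.0
            for r in dict.fromkeys(regions[p] for p in pops):
                members = [p for p in pops if regions[p] == r]
                wr = np.array([table.n_typed[(locus, p)] for p in members], dtype=float)
                mix = np.sum(
                    [wi * vecs[p] for wi, p in zip(wr / wr.sum(), members)], axis=0
                )
                shr += wr.sum() / np.sum(
                    [table.n_typed[(locus, p)] for p in pops]
                ) * _entropy(mix)
            row["sHr"] = shr
            row["I_region_total"] = sht - shr
            row["I_pop_region"] = shr - shs
        rows.append(row)
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        raise ValidationError("no locus typed in every stratum")
    multilocus = {
        c: float(per_locus[c].mean()) for c in per_locus.columns if c != "locus"
    }
    return ShannonPartition(per_locus, multilocus, levels)


def permute_shannon(
    ds: GenotypeDataset,
    m: int = 999,
    seed: int | None = None,
    level: str = "I_pop_total",
) -> ResamplingResult:
    """Permutation test of an information component, one-tailed greater.

    ``I_pop_total`` and ``I_pop_region`` permute individuals among
    populations (within regions for the latter); ``I_region_total`` permutes
    whole populations among regions.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    levels = 3 if level in ("I_region_total", "I_pop_region") else (
        3 if ds.regions is not None else 2
    )
    obs = shannon_partition(ds, levels=levels)[level]
    rng = np.random.default_rng(seed)
    null = np.empty(m)
    pop_arr = np.asarray(ds.pops, dtype=object)
    if level == "I_region_total":
        assert ds.regions is not None
        pop_names = ds.pop_names
        region_values = [ds.regions[p] for p in pop_names]
        for b in range(m):
            rmap = dict(zip(pop_names, rng.permutation(np.asarray(region_values, dtype=object))))
            null[b] = shannon_partition(ds, levels=3, regions=rmap)[level]
    elif level == "I_pop_region":
        assert ds.regions is not None
        region_arr = np.asarray([ds.regions[p] for p in ds.pops], dtype=object)
        for b in range(m):
            labels = pop_arr.copy()
            for r in np.unique(region_arr):
                ix = np.flatnonzero(region_arr == r)
                labels[ix] = labels[ix[rng.permutation(ix.size)]]
            null[b] = shannon_partition(ds.with_pops(list(labels)), levels=3)[level]
    else:
        for b in range(m):
            perm = ds.with_pops(list(rng.permutation(pop_arr)))
            null[b] = shannon_partition(perm, levels=levels)[level]
    return ResamplingResult(
        obs, "permutation", null,
        p_value=permutation_pvalue(obs, null), n_resamples=m, seed=seed,
    )
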