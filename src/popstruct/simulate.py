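"""Seeded generators with known ground truth for every analysis.

Three models cover the package's test surface:

* :func:`sim_island` — island-model codominant genotypes.  Per locus an
  ancestral frequency vector is drawn uniformly on the simplex; population
  frequencies follow the Balding-Nichols compound distribution
  Dirichlet(p_anc (1 - Fst) / Fst), whose expected among-population
  differentiation equals the Fst parameter; genotypes are drawn under HWE
  within populations.
* :func:`sim_haplotypes` — phased two-locus haplotype pairs at a specified
  gametic disequilibrium D, plus the collapsed 3x3 genotype table, for
  exercising phase-known vs EM estimation.
* :func:`sim_spatial` — families of full sibs dropped into spatial clusters
  of a given radius inside a square arena; a smaller radius produces
  stronger fine-scale spatial genetic autocorrelation.

All generators are pure functions of their arguments: the same seed gives
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataType, GenotypeDataset, LocusInfo, ValidationError

__all__ = ["SimConfig", "sim_island", "sim_haplotypes", "sim_spatial", "HaplotypeSim"]


@dataclass
class SimConfig:
    """Bag of generator parameters; unused fields are ignored by each model."""

    seed: int = 0
    k_pops: int = 4
    n_per_pop: int = 30
    L_loci: int = 10
    fst: float = 0.1
    n_alleles: int = 2
    n: int = 1000
    p_a: float = 0.5
    p_b: float = 0.5
    D: float = 0.0
    n_families: int = 20
    family_size: int = 5
    radius: float = 1.0
    extent: float = 100.0
    region_map: dict[str, str] | None = None


def _dataset(alleles, pops, L, regions=None, coords=None, title="simulated"):
    n = alleles.shape[0]
    return GenotypeDataset(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        data_type=DataType.CODOMINANT_DIPLOID,
        loci=[LocusInfo(f"L{l + 1}") for l in range(L)],
        alleles=alleles,
        pops=pops,
        regions=regions,
        coords=coords,
        title=title,
    ).validate()


def sim_island(
    seed: int,
    k_pops: int = 4,
    n_per_pop: int = 30,
    L_loci: int = 10,
    fst: float = 0.1,
    n_alleles: int = 2,
    region_map: dict[str, str] | None = None,
) -> GenotypeDataset:
    """Island-model diploid genotypes with target differentiation ``fst``.

    ``fst`` must lie in (0, 1); pass a tiny value (e.g. 1e-6) for an
    effectively panmictic collection of populations.
    """
    if not (0 < fst < 1):
        raise ValidationError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = k_pops * n_per_pop
    alleles = np.zeros((n, 2 * L_loci), dtype=np.int64)
    scale = (1.0 - fst) / fst
    for l in range(L_loci):
        p_anc = rng.dirichlet(np.ones(n_alleles))
        for g in range(k_pops):
            alpha = np.maximum(p_anc * scale, 1e-9)
            p = rng.dirichlet(alpha)
            draws = rng.choice(n_alleles, size=(n_per_pop, 2), p=p) + 1
            rows = slice(g * n_per_pop, (g + 1) * n_per_pop)
            alleles[rows, 2 * l : 2 * l + 2] = draws
    pops = [f"P{g + 1}" for g in range(k_pops) for _ in range(n_per_pop)]
    return _dataset(alleles, pops, L_loci, regions=region_map, title="island model")


@dataclass
class HaplotypeSim:
    hap_counts: np.ndarray        # (AB, Ab, aB, ab) phased counts
    geno_counts: np.ndarray       # 3x3 two-locus genotype collapse
    hap_probs: np.ndarray
    dataset: GenotypeDataset      # 2-locus diploid dataset (phase discarded)


def sim_haplotypes(
    seed: int, n: int = 1000, p_a: float = 0.5, p_b: float = 0.5, D: float = 0.0
) -> HaplotypeSim:
    """Phased haplotype pairs at disequilibrium ``D`` plus their genotype collapse."""
    pA, pB = p_a, p_b
    qA, qB = 1 - pA, 1 - pB
    probs = np.array([pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D])
    if (probs < -1e-12).any():
        raise ValidationError(f"D={D} inadmissible for margins ({pA}, {pB})")
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    # 2n haplotypes drawn in pairs; codes: hap index 0..3
    haps = rng.choice(4, size=(n, 2), p=probs)
    hap_counts = np.bincount(haps.ravel(), minlength=4).astype(float)
    # allele at locus A: hap 0,1 carry A; at locus B: hap 0,2 carry B
    a_dosage = np.sum(haps >= 2, axis=1)          # copies of allele a
    b_dosage = np.sum((haps == 1) | (haps == 3), axis=1)  # copies of allele b
    geno = np.zeros((3, 3))
    for i, j in zip(a_dosage, b_dosage):
        geno[i, j] += 1
    # genotype dataset with allele codes 1 (A/B) and 2 (a/b)
    alleles = np.empty((n, 4), dtype=np.int64)
    alleles[:, 0] = 1 + (haps[:, 0] >= 2)
    alleles[:, 1] = 1 + (haps[:, 1] >= 2)
    alleles[:, 2] = 1 + ((haps[:, 0] == 1) | (haps[:, 0] == 3))
    alleles[:, 3] = 1 + ((haps[:, 1] == 1) | (haps[:, 1] == 3))
    ds = _dataset(alleles, ["P1"] * n, 2, title="haplotype pairs")
    return HaplotypeSim(hap_counts, geno, probs, ds)


def sim_spatial(
    seed: int,
    n_families: int = 20,
    family_size: int = 5,
    L_loci: int = 10,
    n_alleles: int = 8,
    radius: float = 1.0,
    extent: float = 100.0,
) -> GenotypeDataset:
    """Family clusters in a square arena of side ``extent``.

    Each family is a sibship from one random parent pair, all members placed
    within ``radius`` of the family's cluster center.  Small radii put close
    relatives at short mutual distances (positive fine-scale autocorrelation);
    a radius comparable to ``extent`` approaches spatial randomness.
    """
    rng = np.random.default_rng(seed)
    n = n_families * family_size
    alleles = np.zeros((n, 2 * L_loci), dtype=np.int64)
    coords = np.zeros((n, 2))
    row = 0
    for _ in range(n_families):
        center = rng.uniform(0, extent, 2)
        parents = rng.integers(1, n_alleles + 1, size=(2, 2 * L_loci))
        for _ in range(family_size):
            for l in range(L_loci):
                m_allele = parents[0, 2 * l + rng.integers(2)]
                p_allele = parents[1, 2 * l + rng.integers(2)]
                alleles[row, 2 * l : 2 * l + 2] = (m_allele, p_allele)
            offset = rng.uniform(-radius, radius, 2)
            coords[row] = np.clip(center + offset, 0, extent)
            row += 1
    return _dataset(
        alleles, ["P1"] * n, L_loci, coords=coords, title="spatial families"
    )


def from_config(model: str, cfg: SimConfig):
    """Dispatch a SimConfig to the matching generator (CLI/YAML entry point)."""
    if model == "island":
        return sim_island(cfg.seed, cfg.k_pops, cfg.n_per_pop, cfg.L_loci,
                          cfg.fst, cfg.n_alleles, cfg.region_map)
    if model == "haplotypes":
        return sim_haplotypes(cfg.seed, cfg.n, cfg.p_a, cfg.p_b, cfg.D)
    if model == "spatial":
        return sim_spatial(cfg.seed, cfg.n_families, cfg.family_size,
                           cfg.L_loci, cfg.n_alleles, cfg.radius, cfg.extent)
    raise ValidationError(f"unknown model {model!r}")
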