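"""Canonical in-memory data model for genotype datasets.

The central container is :class:`GenotypeDataset`: a samples x loci integer
allele matrix with a population partition, an optional region partition over
populations, and optional spatial coordinates.  Three marker systems are
supported:

``codominant_diploid``
    Two adjacent allele columns per locus (e.g. microsatellites); allele
    codes are positive integers, 0 marks a missing genotype (both columns 0).
``haploid``
    One allele column per locus; 0 = missing.
``binary``
    One presence/absence column per locus (e.g. AFLP bands).  In files the
    missing code is 0 like everywhere else, but internally missing is stored
    as -1 so that 0 remains a valid band-absence state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DataType",
    "LocusInfo",
    "GenotypeDataset",
    "AlleleFreqTable",
    "DistanceMatrix",
    "ResamplingResult",
    "ValidationError",
    "validate_dataset",
    "split_by_population",
    "allele_frequencies",
]

MISSING_BINARY = -1


class ValidationError(ValueError):
    """A dataset violates one of the structural invariants."""


class DataType(str, enum.Enum):
    CODOMINANT_DIPLOID = "codominant_diploid"
    HAPLOID = "haploid"
    BINARY = "binary"

    @property
    def ploidy(self) -> int:
        return 2 if self is DataType.CODOMINANT_DIPLOID else 1


@dataclass(frozen=True)
class LocusInfo:
    name: str
    observed_alleles: tuple[int, ...] = ()


@dataclass
class GenotypeDataset:
    """Samples x loci allele matrix with population/region structure.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``alleles``.
    data_type
        Marker system; fixes the ploidy and the column layout.
    loci
        Locus metadata; ``alleles`` has ``ploidy * len(loci)`` columns,
        adjacent pairs for diploid data.
    alleles
        Integer matrix.  Missing is 0 (codominant/haploid) or -1 (binary).
    pops
        Population label per sample.  Population order is order of first
        appearance and is preserved by every operation.
    regions
        Optional map population label -> region label.
    coords
        Optional (n, 2) array of x/y coordinates.
    """

    sample_ids: list[str]
    data_type: DataType
    loci: list[LocusInfo]
    alleles: np.ndarray
    pops: list[str]
    regions: dict[str, str] | None = None
    coords: np.ndarray | None = None
    title: str = "popstruct dataset"

    # -- structure ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ploidy(self) -> int:
        return self.data_type.ploidy

    @property
    def missing_code(self) -> int:
        return MISSING_BINARY if self.data_type is DataType.BINARY else 0

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def region_names(self) -> list[str]:
        if self.regions is None:
            return []
        seen: dict[str, None] = {}
        for p in self.pop_names:
            seen.setdefault(self.regions[p], None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pops])
        return np.flatnonzero(mask)

    def locus_columns(self, locus_index: int) -> np.ndarray:
        """Allele columns for one locus, shape (n_samples, ploidy)."""
        k = self.ploidy
        return self.alleles[:, locus_index * k : locus_index * k + k]

    def region_of_sample(self, i: int) -> str:
        assert self.regions is not None
        return self.regions[self.pops[i]]

    # -- validation --------------------------------------------------------

    def validate(self) -> "GenotypeDataset":
        n, L, k = self.n_samples, self.n_loci, self.ploidy
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample id(s): {dup}")
        if self.alleles.shape != (n, k * L):
            raise ValidationError(
                f"allele matrix shape {self.alleles.shape} != ({n}, {k * L})"
            )
        if len(self.pops) != n:
            raise ValidationError("one population label required per sample")
        names = [l.name for l in self.loci]
        if len(set(names)) != L:
            raise ValidationError("locus names must be unique")
        if self.data_type is DataType.BINARY:
            ok = np.isin(self.alleles, (MISSING_BINARY, 0, 1))
            if not ok.all():
                bad = np.unique(self.alleles[~ok])
                raise ValidationError(f"binary entries outside {{0,1,missing}}: {bad}")
        else:
            if (self.alleles < 0).any():
                raise ValidationError("allele codes must be >= 0 (0 = missing)")
        if self.data_type is DataType.CODOMINANT_DIPLOID:
            a = self.alleles.reshape(n, L, 2)
            half = (a == 0).sum(axis=2) == 1
            if half.any():
                i, l = map(int, np.argwhere(half)[0])
                raise ValidationError(
                    f"half-missing genotype: sample {self.sample_ids[i]!r}, "
                    f"locus {names[l]!r}"
                )
        for p in self.pop_names:
            if len(self.pop_indices(p)) == 0:
                raise ValidationError(f"population {p!r} has 0 samples")
        if self.regions is not None:
            missing = [p for p in self.pop_names if p not in self.regions]
            if missing:
                raise ValidationError(f"populations without region: {missing}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValidationError("coords must be (n_samples, 2)")
            if not np.isfinite(self.coords).all():
                raise ValidationError("coordinates must be finite for all samples")
        # populate observed alleles from the data
        new_loci = []
        for l in range(L):
            cols = self.locus_columns(l)
            obs = np.unique(cols[cols != self.missing_code])
            new_loci.append(LocusInfo(names[l], tuple(int(x) for x in obs)))
        self.loci = new_loci
        return self

    def subset(self, idx: np.ndarray, keep_regions: bool = True) -> "GenotypeDataset":
        """Row subset preserving locus metadata and label order."""
        idx = np.asarray(idx)
        pops = [self.pops[i] for i in idx]
        regions = None
        if keep_regions and self.regions is not None:
            regions = {p: self.regions[p] for p in dict.fromkeys(pops)}
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            data_type=self.data_type,
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
            pops=pops,
            regions=regions,
            coords=None if self.coords is None else self.coords[idx].copy(),
            title=self.title,
        )

    def with_pops(self, pops: list[str]) -> "GenotypeDataset":
        return replace(self, pops=list(pops))

    def subset_loci(self, locus_indices) -> "GenotypeDataset":
        """Column subset (loci may repeat, e.g. bootstrap over loci)."""
        k = self.ploidy
        cols = []
        loci = []
        for j, l in enumerate(locus_indices):
            cols.extend(range(l * k, l * k + k))
            info = self.loci[l]
            # repeated loci need distinct names to stay addressable
            name = info.name if info.name not in [x.name for x in loci] else f"{info.name}.{j}"
            loci.append(LocusInfo(name, info.observed_alleles))
        return replace(self, loci=loci, alleles=self.alleles[:, cols].copy())


def validate_dataset(ds: GenotypeDataset) -> GenotypeDataset:
    """Validate structural invariants and populate observed alleles."""
    return ds.validate()


def split_by_population(ds: GenotypeDataset) -> dict[str, GenotypeDataset]:
    """One dataset per population, in population order; locus metadata kept."""
    return {p: ds.subset(ds.pop_indices(p)) for p in ds.pop_names}


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFreqTable:
    """Per-(locus, population) allele relative frequencies.

    ``freqs[(locus, pop)]`` maps allele code -> relative frequency among the
    ``n_typed[(locus, pop)]`` non-missing gene copies.  A (locus, pop) cell
    with zero typed copies is simply absent (never 0/0).  ``from_genotypes``
    records whether the table was counted from genotypes (enabling
    sample-size corrections downstream) or loaded as published frequencies.
    """

    loci: list[str]
    pops: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n_typed: dict[tuple[str, str], int]
    from_genotypes: bool = True
    ploidy: int = 2

    def alleles_at(self, locus: str) -> list[int]:
        out: set[int] = set()
        for p in self.pops:
            out.update(self.freqs.get((locus, p), {}))
        return sorted(out)

    def freq_vector(self, locus: str, pop: str, alleles: list[int] | None = None) -> np.ndarray | None:
        cell = self.freqs.get((locus, pop))
        if cell is None:
            return None
        if alleles is None:
            alleles = self.alleles_at(locus)
        return np.array([cell.get(a, 0.0) for a in alleles])

    def pooled(self, locus: str, weighted: bool = True) -> dict[int, float]:
        """Mean frequency across populations (gene-copy weighted or unweighted)."""
        alleles = self.alleles_at(locus)
        tot = np.zeros(len(alleles))
        wsum = 0.0
        for p in self.pops:
            v = self.freq_vector(locus, p, alleles)
            if v is None:
                continue
            w = self.n_typed[(locus, p)] if weighted else 1.0
            tot += w * v
            wsum += w
        if wsum == 0:
            return {}
        tot /= wsum
        return {a: float(f) for a, f in zip(alleles, tot)}


def allele_frequencies(ds: GenotypeDataset) -> AlleleFreqTable:
    """Count allele relative frequencies from non-missing gene copies."""
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    for l, locus in enumerate(ds.locus_names):
        cols = ds.alleles[:, l * ds.ploidy : (l + 1) * ds.ploidy]
        for pop in ds.pop_names:
            sub = cols[ds.pop_indices(pop)]
            vals = sub[sub != ds.missing_code]
            if vals.size == 0:
                continue
            codes, counts = np.unique(vals, return_counts=True)
            n = int(vals.size)
            freqs[(locus, pop)] = {
                int(c): float(k) / n for c, k in zip(codes, counts)
            }
            n_typed[(locus, pop)] = n
    return AlleleFreqTable(
        loci=list(ds.locus_names),
        pops=list(ds.pop_names),
        freqs=freqs,
        n_typed=n_typed,
        from_genotypes=True,
        ploidy=ds.ploidy,
    )


# ---------------------------------------------------------------------------
# shared result containers


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise squared distances with entity labels."""

    labels: list[str]
    d2: np.ndarray
    kind: str = "individual"  # or "population"

    def __post_init__(self) -> None:
        self.d2 = np.asarray(self.d2, dtype=float)
        n = len(self.labels)
        if self.d2.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch with labels")
        if not np.array_equal(self.d2, self.d2.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.diag(self.d2).any():
            raise ValidationError("distance matrix diagonal must be 0")
        if (self.d2 < 0).any():
            raise ValidationError("squared distances must be non-negative")


@dataclass
class ResamplingResult:
    """Observed statistic plus a permutation null, jackknife SE or bootstrap CI."""

    observed: float
    mode: str  # permutation | jackknife_loci | bootstrap_loci
    replicates: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_resamples: int = 0
    seed: int | None = None


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """One-tailed (greater) Monte-Carlo p-value: (b + 1) / (m + 1)."""
    null = np.asarray(null, dtype=float)
    b = int(np.sum(null >= observed))
    return (b + 1) / (null.size + 1)
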