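"""Individual genotypic distance matrices, PCoA and Mantel machinery.

The codominant squared distance between two single-locus diploid genotypes
is half the squared Euclidean distance between their allele-count vectors,
which reproduces the classic seven-case table for distinct alleles i,j,k,l:

    d2(ii,ii)=0  d2(ij,ij)=0  d2(ii,ij)=1  d2(ij,ik)=1
    d2(ii,jj)=4  d2(ii,jk)=3  d2(ij,kl)=2

Multilocus distance is the sum over loci typed in both individuals, rescaled
by L / L_shared so that pairs with missing data stay comparable.  Haploid
and binary distances are mismatch counts (squared Euclidean for 0/1 bands),
with missing loci excluded pairwise under the same rescaling.

PCoA is the eigen-decomposition of the Gower-centered matrix
C = -1/2 (d2 - rowmean_i - rowmean_j + grandmean); C also feeds the spatial
autocorrelation module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .core import (
    DataType,
    DistanceMatrix,
    GenotypeDataset,
    ValidationError,
    permutation_pvalue,
)

__all__ = [
    "codominant_distance",
    "haploid_distance",
    "binary_distance",
    "genotype_distance",
    "gower_center",
    "pcoa",
    "PcoaResult",
    "mantel",
    "MantelResult",
    "compare_pairwise_stats",
]


def _accumulate(ds: GenotypeDataset, per_locus) -> DistanceMatrix:
    """Sum per-locus d2 where both typed; rescale by L / L_shared."""
    n, L = ds.n_samples, ds.n_loci
    total = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l in range(L):
        d2_l, typed = per_locus(l)  # (n, n) contribution, (n,) typed mask
        both = np.outer(typed, typed)
        total += np.where(both, d2_l, 0.0)
        shared += both
    untyped = np.flatnonzero(shared.diagonal() == 0)
    if untyped.size:
        raise ValidationError(
            f"individual(s) with no typed locus: {[ds.sample_ids[i] for i in untyped]}"
        )
    off = ~np.eye(n, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValidationError(
            f"samples {ds.sample_ids[i]!r} and {ds.sample_ids[j]!r} share no typed locus"
        )
    d2 = total * (L / shared)
    np.fill_diagonal(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0  # exact symmetry
    return DistanceMatrix(list(ds.sample_ids), d2, kind="individual")


def codominant_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise squared genotypic distance for codominant diploid data."""
    if ds.data_type is not DataType.CODOMINANT_DIPLOID:
        raise ValidationError("codominant distance requires diploid data")
    n = ds.n_samples

    def per_locus(l):
        g = ds.locus_columns(l)
        typed = (g != 0).all(axis=1)
        alleles = np.unique(g[g != 0])
        counts = np.zeros((n, alleles.size))
        for a_idx, a in enumerate(alleles):
            counts[:, a_idx] = (g == a).sum(axis=1)
        sq = np.sum(counts**2, axis=1)
        d2 = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * counts @ counts.T)
        return np.maximum(d2, 0.0), typed

    return _accumulate(ds, per_locus)


def haploid_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Mismatch-count distance for haploid data."""
    if ds.data_type is not DataType.HAPLOID:
        raise ValidationError("haploid distance requires haploid data")

    def per_locus(l):
        g = ds.locus_columns(l)[:, 0]
        typed = g != 0
        d2 = (g[:, None] != g[None, :]).astype(float)
        return d2, typed

    return _accumulate(ds, per_locus)


def binary_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Squared Euclidean (= mismatch count) distance for 0/1 band data."""
    if ds.data_type is not DataType.BINARY:
        raise ValidationError("binary distance requires binary data")

    def per_locus(l):
        g = ds.locus_columns(l)[:, 0]
        typed = g != ds.missing_code
        d2 = (g[:, None] != g[None, :]).astype(float)
        return d2, typed

    return _accumulate(ds, per_locus)


def genotype_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """Dispatch to the metric matching the dataset's marker system."""
    return {
        DataType.CODOMINANT_DIPLOID: codominant_distance,
        DataType.HAPLOID: haploid_distance,
        DataType.BINARY: binary_distance,
    }[ds.data_type](ds)


def gower_center(d2: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Double-centered covariance form: c_ij = -1/2 (d2_ij - ri - rj + g)."""
    m = d2.d2 if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    row = m.mean(axis=1)
    c = -0.5 * (m - row[:, None] - row[None, :] + m.mean())
    return (c + c.T) / 2.0


@dataclass
class PcoaResult:
    labels: list[str]
    eigenvalues: np.ndarray        # all, descending
    coordinates: np.ndarray        # (n, n_positive_axes)
    percent_variance: np.ndarray   # over positive eigenvalues, sums to 100

    def as_frame(self) -> pd.DataFrame:
        cols = [f"Axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(d2: DistanceMatrix, eps: float = 1e-9) -> PcoaResult:
    """Metric ordination of a squared-distance matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues;
    negative eigenvalues are reported but excluded from percent variance.
    Axis sign convention: the first nonzero loading of each axis is positive.
    """
    c = gower_center(d2)
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for a in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, a]) > 1e-12)
        if nz.size and coords[nz[0], a] < 0:
            coords[:, a] = -coords[:, a]
    pv = 100.0 * vals[pos] / vals[pos].sum() if pos.any() else np.empty(0)
    return PcoaResult(list(d2.labels), vals, coords, pv)


@dataclass
class MantelResult:
    r: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    tail: str = "greater"


def _triangle(m: np.ndarray) -> np.ndarray:
    return squareform(m, checks=False)


def mantel(
    a: np.ndarray | DistanceMatrix | pd.DataFrame,
    b: np.ndarray | DistanceMatrix | pd.DataFrame,
    m: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Matrix correlation with a joint row/column permutation test.

    rM is the Pearson correlation of the upper off-diagonal triangles;
    the null shuffles the label order of B.  ``tail`` is ``"greater"``
    (signed, default) or ``"two-sided"`` (on |rM|).
    """

    def to_array(x):
        if isinstance(x, DistanceMatrix):
            return x.d2
        if isinstance(x, pd.DataFrame):
            return x.to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    A, B = to_array(a), to_array(b)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValidationError("mantel requires two square matrices of equal size")
    np.fill_diagonal(A := A.copy(), 0.0)
    np.fill_diagonal(B := B.copy(), 0.0)
    ta = _triangle(A)
    if ta.std() == 0 or _triangle(B).std() == 0:
        raise ValidationError("matrix with constant off-diagonal: rM undefined")

    def corr(Bperm):
        return float(np.corrcoef(ta, _triangle(Bperm))[0, 1])

    r_obs = corr(B)
    if m <= 0:
        return MantelResult(r_obs, None, 0, seed, tail)
    rng = np.random.default_rng(seed)
    null = np.empty(m)
    n = A.shape[0]
    for i in range(m):
        perm = rng.permutation(n)
        null[i] = corr(B[np.ix_(perm, perm)])
    if tail == "two-sided":
        p = permutation_pvalue(abs(r_obs), np.abs(null))
    else:
        p = permutation_pvalue(r_obs, null)
    return MantelResult(r_obs, p, m, seed, tail)


def compare_pairwise_stats(
    ds: GenotypeDataset,
    statistics: list[str],
    m: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], MantelResult]]:
    """Mantel comparison of pairwise-population matrices of several statistics.

    Returns (rM table, p-value table, per-pair MantelResult map); a statistic
    whose matrix is undefined anywhere is flagged with NaN rows/columns.
    """
    from .differentiation import pairwise_matrix

    mats = {s: pairwise_matrix(ds, s).to_numpy() for s in statistics}
    k = len(statistics)
    r_tab = np.full((k, k), np.nan)
    p_tab = np.full((k, k), np.nan)
    results: dict[tuple[str, str], MantelResult] = {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(k * k)
    for i, s1 in enumerate(statistics):
        r_tab[i, i] = 1.0
        for j in range(i + 1, k):
            s2 = statistics[j]
            if np.isnan(mats[s1]).any() or np.isnan(mats[s2]).any():
                continue
            try:
                res = mantel(mats[s1], mats[s2], m=m, seed=int(seeds[i * k + j]))
            except ValidationError:
                continue
            results[(s1, s2)] = res
            r_tab[i, j] = r_tab[j, i] = res.r
            p_tab[i, j] = p_tab[j, i] = res.p_value if res.p_value is not None else np.nan
    idx = list(statistics)
    return (
        pd.DataFrame(r_tab, index=idx, columns=idx),
        pd.DataFrame(p_tab, index=idx, columns=idx),
        results,
    )
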