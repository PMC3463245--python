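"""Multilocus spatial autocorrelation and heterogeneity tests.

The autocorrelation coefficient for a geographic distance class h is a
covariance ratio computed from the Gower-centered genotypic matrix
C (c_ij between-individual covariance, c_ii within-individual variance):

    r_h = 2 * sum_{(i,j) in S_h} c_ij  /  sum_i w_i c_ii

where S_h is the set of individual pairs whose geographic distance falls in
class h and w_i counts the pairs in S_h that involve individual i.  r_h lies
in [-1, 1]; positive values mean individuals in that distance class are
genetically more alike than random pairs.

Uncertainty is assessed two ways, as is conventional for correlograms:
a permutation null (shuffling genotypes against coordinates) yields a 95%
envelope around r = 0, and bootstrapping pairs within each class yields a
95% CI around the estimate.

Heterogeneity between correlograms computed on separate datasets (same
distance classes) is tested with the squared standardized class difference

    t2_h = sum_d (r_dh - rbar_h)^2 / varbar_h

(varbar_h = mean permutation variance of r_h across datasets; for two
datasets this is (r1 - r2)^2 / (var1 + var2)) and the whole-correlogram
statistic omega = sum_h t2_h.  Significance comes from permuting dataset
membership of whole individuals (genotype and coordinates move together),
holding the variance scaling fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from contextlib import contextmanager

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import GenotypeDataset, ValidationError, permutation_pvalue
from .distance import genotype_distance, gower_center

__all__ = [
    "DistanceClassSpec",
    "AutocorrResult",
    "autocorrelation",
    "HeterogeneityResult",
    "heterogeneity_test",
]


@contextmanager
def _quiet_nan():
    """Empty distance classes reduce over all-NaN slices; that is expected."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@dataclass(frozen=True)
class DistanceClassSpec:
    """Half-open distance classes (lo, hi]; the first is closed at its lower bound."""

    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        if b.size < 2 or (np.diff(b) <= 0).any():
            raise ValidationError("breaks must be >= 2 strictly ascending values")

    @classmethod
    def even(cls, n_classes: int, max_distance: float) -> "DistanceClassSpec":
        return cls(tuple(np.linspace(0.0, max_distance, n_classes + 1)))

    @property
    def n_classes(self) -> int:
        return len(self.breaks) - 1

    def classify(self, d: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for out-of-range."""
        b = np.asarray(self.breaks)
        idx = np.searchsorted(b, d, side="left") - 1
        idx[np.asarray(d) == b[0]] = 0
        idx[(d < b[0]) | (d > b[-1])] = -1
        return idx


def _class_pairs(coords: np.ndarray, spec: DistanceClassSpec):
    """Per class: (i_idx, j_idx) pair arrays and per-individual pair counts."""
    n = coords.shape[0]
    iu = np.triu_indices(n, 1)
    d = pdist(coords)
    cls = spec.classify(d)
    out = []
    for h in range(spec.n_classes):
        sel = cls == h
        i_idx, j_idx = iu[0][sel], iu[1][sel]
        w = np.bincount(np.concatenate([i_idx, j_idx]), minlength=n).astype(float)
        out.append((i_idx, j_idx, w))
    return out


def _r_per_class(c: np.ndarray, pairs, perm: np.ndarray | None = None) -> np.ndarray:
    diag = np.diag(c)
    rs = np.empty(len(pairs))
    for h, (i_idx, j_idx, w) in enumerate(pairs):
        if i_idx.size == 0:
            rs[h] = math.nan
            continue
        if perm is None:
            num = 2.0 * c[i_idx, j_idx].sum()
            den = float(w @ diag)
        else:
            num = 2.0 * c[perm[i_idx], perm[j_idx]].sum()
            den = float(w @ diag[perm])
        rs[h] = num / den if den > 0 else math.nan
    return rs


@dataclass
class AutocorrResult:
    spec: DistanceClassSpec
    table: pd.DataFrame   # class_lo, class_hi, n_pairs, r, env_low/high, ci_low/high
    null_r: np.ndarray    # (m, n_classes) permutation null values
    seed: int | None = None

    @property
    def r(self) -> np.ndarray:
        return self.table["r"].to_numpy()

    def null_variance(self) -> np.ndarray:
        with _quiet_nan():
            return np.nanvar(self.null_r, axis=0, ddof=1)


def autocorrelation(
    ds: GenotypeDataset,
    spec: DistanceClassSpec | int,
    m_permutations: int = 999,
    b_bootstraps: int = 999,
    seed: int | None = None,
) -> AutocorrResult:
    """Correlogram r per distance class with permutation envelope and bootstrap CI."""
    if ds.coords is None:
        raise ValidationError("spatial autocorrelation requires coordinates")
    if isinstance(spec, int):
        spec = DistanceClassSpec.even(spec, float(pdist(ds.coords).max()))
    c = gower_center(genotype_distance(ds))
    if not (np.diag(c) > 1e-12).any():
        raise ValidationError("zero genotypic variance: r undefined")
    pairs = _class_pairs(ds.coords, spec)
    r_obs = _r_per_class(c, pairs)
    rng = np.random.default_rng(seed)
    n = ds.n_samples
    null = np.empty((m_permutations, spec.n_classes))
    for b in range(m_permutations):
        null[b] = _r_per_class(c, pairs, rng.permutation(n))
    with _quiet_nan():
        env = (np.nanpercentile(null, [2.5, 97.5], axis=0) if m_permutations
               else np.full((2, spec.n_classes), np.nan))
    ci = np.full((2, spec.n_classes), np.nan)
    diag = np.diag(c)
    for h, (i_idx, j_idx, w) in enumerate(pairs):
        if i_idx.size == 0 or b_bootstraps == 0:
            continue
        reps = np.empty(b_bootstraps)
        for b in range(b_bootstraps):
            pick = rng.integers(0, i_idx.size, size=i_idx.size)
            bi, bj = i_idx[pick], j_idx[pick]
            wb = np.bincount(np.concatenate([bi, bj]), minlength=n).astype(float)
            den = float(wb @ diag)
            reps[b] = 2.0 * c[bi, bj].sum() / den if den > 0 else np.nan
        with _quiet_nan():
            ci[:, h] = np.nanpercentile(reps, [2.5, 97.5])
    table = pd.DataFrame(
        dict(
            class_lo=spec.breaks[:-1],
            class_hi=spec.breaks[1:],
            n_pairs=[p[0].size for p in pairs],
            r=r_obs,
            env_low=env[0],
            env_high=env[1],
            ci_low=ci[0],
            ci_high=ci[1],
        )
    )
    return AutocorrResult(spec, table, null, seed)


@dataclass
class HeterogeneityResult:
    t2: np.ndarray
    t2_p: np.ndarray
    omega: float
    omega_p: float
    n_datasets: int
    spec: DistanceClassSpec | None = None
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _t2_omega(r_by_dataset: np.ndarray, var_pooled: np.ndarray) -> tuple[np.ndarray, float]:
    with _quiet_nan():
        rbar = np.nanmean(r_by_dataset, axis=0)
        t2 = np.nansum((r_by_dataset - rbar) ** 2, axis=0) / var_pooled
    return t2, float(np.nansum(t2))


def heterogeneity_test(
    datasets: list[GenotypeDataset],
    spec: DistanceClassSpec,
    m: int = 999,
    seed: int | None = None,
    m_r: int = 99,
) -> HeterogeneityResult:
    """Single-class t2 and whole-correlogram omega heterogeneity tests.

    All datasets must share the same loci and the same class specification.
    ``m_r`` permutations per dataset estimate the variance of r_h used for
    standardization; ``m`` membership permutations drive the p-values.
    """
    if len(datasets) < 2:
        raise ValidationError("heterogeneity test needs >= 2 datasets")
    if m < 1:
        raise ValidationError("m must be >= 1")
    names = [tuple(d.locus_names) for d in datasets]
    if len(set(names)) != 1:
        raise ValidationError("datasets must share the same loci")
    for d in datasets:
        if d.coords is None:
            raise ValidationError("all datasets need coordinates")

    # pooled genotype distance so membership permutations reuse one matrix
    pooled = datasets[0]
    sizes = [d.n_samples for d in datasets]
    offs = np.cumsum([0] + sizes)
    merged = GenotypeDataset(
        sample_ids=[f"d{di}_{s}" for di, d in enumerate(datasets) for s in d.sample_ids],
        data_type=pooled.data_type,
        loci=list(pooled.loci),
        alleles=np.vstack([d.alleles for d in datasets]),
        pops=[f"d{di}" for di, d in enumerate(datasets) for _ in d.sample_ids],
        coords=np.vstack([d.coords for d in datasets]),
        title="pooled",
    ).validate()
    d2_pool = genotype_distance(merged).d2
    coords_pool = merged.coords
    member = np.concatenate([np.full(s, di) for di, s in enumerate(sizes)])
    rng = np.random.default_rng(seed)

    def dataset_r(idx: np.ndarray, rng_local, m_null: int):
        c = gower_center(d2_pool[np.ix_(idx, idx)])
        pairs = _class_pairs(coords_pool[idx], spec)
        r = _r_per_class(c, pairs)
        null = np.empty((m_null, spec.n_classes))
        for b in range(m_null):
            null[b] = _r_per_class(c, pairs, rng_local.permutation(idx.size))
        return r, null

    r_obs = np.empty((len(datasets), spec.n_classes))
    var = np.empty((len(datasets), spec.n_classes))
    for di in range(len(datasets)):
        idx = np.arange(offs[di], offs[di + 1])
        r, null = dataset_r(idx, rng, m_r)
        r_obs[di] = r
        with _quiet_nan():
            var[di] = np.nanvar(null, axis=0, ddof=1)
    with _quiet_nan():
        var_pooled = np.nanmean(var, axis=0)
    var_pooled = np.where(var_pooled > 0, var_pooled, np.nan)
    t2_obs, omega_obs = _t2_omega(r_obs, var_pooled)

    null_t2 = np.empty((m, spec.n_classes))
    null_omega = np.empty(m)
    for b in range(m):
        perm_member = rng.permutation(member)
        r_perm = np.empty_like(r_obs)
        for di in range(len(datasets)):
            idx = np.flatnonzero(perm_member == di)
            c = gower_center(d2_pool[np.ix_(idx, idx)])
            pairs = _class_pairs(coords_pool[idx], spec)
            r_perm[di] = _r_per_class(c, pairs)
        null_t2[b], null_omega[b] = _t2_omega(r_perm, var_pooled)
    t2_p = np.array([
        permutation_pvalue(t2_obs[h], null_t2[:, h]) if not math.isnan(t2_obs[h]) else math.nan
        for h in range(spec.n_classes)
    ])
    omega_p = permutation_pvalue(omega_obs, null_omega)
    table = pd.DataFrame(
        dict(class_lo=spec.breaks[:-1], class_hi=spec.breaks[1:], t2=t2_obs, p=t2_p)
    )
    return HeterogeneityResult(t2_obs, t2_p, omega_obs, omega_p, len(datasets), spec, table)
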