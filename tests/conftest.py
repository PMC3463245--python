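import numpy as np
import pytest

from popstruct.core import DataType, GenotypeDataset, LocusInfo


def make_diploid(genotypes, pops, regions=None, coords=None, locus_names=None,
                 sample_ids=None, validate=True):
    """Build a diploid dataset from a nested list of per-sample allele rows.

    ``genotypes[i]`` is the flat allele row of sample i: two entries per
    locus, 0 = missing.
    """
    alleles = np.asarray(genotypes, dtype=np.int64)
    n, cols = alleles.shape
    L = cols // 2
    ds = GenotypeDataset(
        sample_ids=sample_ids or [f"S{i + 1}" for i in range(n)],
        data_type=DataType.CODOMINANT_DIPLOID,
        loci=[LocusInfo(nm) for nm in (locus_names or [f"L{l + 1}" for l in range(L)])],
        alleles=alleles,
        pops=list(pops),
        regions=regions,
        coords=None if coords is None else np.asarray(coords, dtype=float),
    )
    return ds.validate() if validate else ds


def make_haploid(genotypes, pops, **kw):
    alleles = np.asarray(genotypes, dtype=np.int64)
    n, L = alleles.shape
    ds = GenotypeDataset(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        data_type=DataType.HAPLOID,
        loci=[LocusInfo(f"L{l + 1}") for l in range(L)],
        alleles=alleles,
        pops=list(pops),
        **kw,
    )
    return ds.validate()


@pytest.fixture
def two_pops_fixed():
    """Two populations fixed for different alleles at every locus."""
    rows = [[1, 1, 3, 3]] * 4 + [[2, 2, 4, 4]] * 4
    return make_diploid(rows, ["A"] * 4 + ["B"] * 4)


@pytest.fixture
def identical_pops():
    """Three populations with identical genotype composition."""
    block = [[1, 1, 1, 2], [1, 2, 2, 2], [2, 2, 1, 1], [1, 2, 1, 2]]
    return make_diploid(block * 3, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)


@pytest.fixture(scope="session")
def island_fixture():
    from popstruct.simulate import sim_island

    return sim_island(seed=11, k_pops=4, n_per_pop=20, L_loci=8, fst=0.15,
                      n_alleles=4)
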