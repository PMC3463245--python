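import math
import warnings

import numpy as np
import pytest

from popstruct.core import AlleleFreqTable, ValidationError
from popstruct.differentiation import (
    differentiation,
    multilocus_stat,
    nei_chesser_hs_ht,
    pairwise_matrix,
    resample,
)

from conftest import make_diploid


def freq_table(freq_map, n=20):
    """Frequency-only table; freq_map: pop -> {allele: p} for one locus."""
    return AlleleFreqTable(
        loci=["L1"],
        pops=list(freq_map),
        freqs={("L1", p): dict(v) for p, v in freq_map.items()},
        n_typed={("L1", p): n for p in freq_map},
        from_genotypes=False,
    )


class TestHsHt:
    def test_fixed_pops_uncorrected(self):
        t = freq_table({"A": {1: 1.0}, "B": {2: 1.0}})
        hs, ht, k, corrected = nei_chesser_hs_ht(t, "L1")
        assert (hs, ht, k, corrected) == (0.0, 0.5, 2, False)

    def test_identical_pops_hs_equals_ht(self):
        t = freq_table({"A": {1: 0.4, 2: 0.6}, "B": {1: 0.4, 2: 0.6}})
        hs, ht, _, _ = nei_chesser_hs_ht(t, "L1")
        assert hs == pytest.approx(ht, abs=1e-15)

    def test_hand_computed_070_030(self):
        t = freq_table({"A": {1: 0.7, 2: 0.3}, "B": {1: 0.3, 2: 0.7}})
        hs, ht, _, _ = nei_chesser_hs_ht(t, "L1")
        assert hs == pytest.approx(0.42)
        assert ht == pytest.approx(0.5)


class TestEstimates:
    def test_maximal_differentiation_fixed_point(self, two_pops_fixed):
        m = differentiation(two_pops_fixed).multilocus
        for s in ("Gst", "Gprime_st", "Gpprime_st", "Dest"):
            assert m[s] == pytest.approx(1.0, abs=1e-12), s

    def test_identical_frequencies_all_zero(self):
        t = freq_table({"A": {1: 0.4, 2: 0.6}, "B": {1: 0.4, 2: 0.6}})
        m = differentiation(t).multilocus
        for s in ("Gst", "Gprime_st", "Gpprime_st", "Dest"):
            assert m[s] == pytest.approx(0.0, abs=1e-12), s

    def test_hand_substituted_values(self):
        t = freq_table({"A": {1: 0.7, 2: 0.3}, "B": {1: 0.3, 2: 0.7}})
        m = differentiation(t).multilocus
        assert m["Gst"] == pytest.approx(0.16)
        assert m["Dest"] == pytest.approx(2 * 0.08 / 0.58)
        assert m["Gprime_st"] == pytest.approx(0.16 * 1.42 / 0.58)

    def test_monomorphic_locus_excluded_with_warning(self):
        rows = [[1, 1, 5, 5], [1, 2, 5, 5], [2, 2, 5, 5], [1, 2, 5, 5]]
        ds = make_diploid(rows, ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="monomorphic"):
            est = differentiation(ds)
        assert len(est.per_locus) == 2
        assert not math.isnan(est.multilocus["Dest"])

    def test_requires_two_pops(self):
        with pytest.raises(ValidationError):
            differentiation(freq_table({"A": {1: 1.0}}))

    @pytest.mark.parametrize("seed", range(8))
    def test_gprime_dominates_gst_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        fm = {}
        for pop in ("A", "B", "C"):
            p = rng.dirichlet(np.ones(4))
            fm[pop] = {i + 1: float(x) for i, x in enumerate(p)}
        m = differentiation(freq_table(fm)).multilocus
        if 0 < m["Hs"] < 1 and m["Gst"] > 0:
            assert m["Gprime_st"] >= m["Gst"] - 1e-12


class TestPairwise:
    @staticmethod
    def _freq_only(ds):
        from popstruct.core import allele_frequencies

        t = allele_frequencies(ds)
        t.from_genotypes = False  # uncorrected mode: zero identity is exact
        return t

    def test_identical_pops_zero_matrix(self, identical_pops):
        m = pairwise_matrix(self._freq_only(identical_pops), "Dest")
        assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_identical_pops_near_zero_with_corrections(self, identical_pops):
        # small-sample corrections leave genotype-mode estimates within
        # O(1/n) of zero, reported as computed (never truncated)
        m = pairwise_matrix(identical_pops, "Dest").to_numpy()
        off = m[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_two_identical_one_fixed_different(self):
        block = [[1, 2], [1, 1], [2, 2], [1, 2]]
        rows = block + block + [[3, 3]] * 4
        ds = make_diploid(rows, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        m = pairwise_matrix(self._freq_only(ds), "Dest")
        assert m.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert m.loc["A", "C"] == pytest.approx(1.0, abs=1e-12)
        assert m.loc["B", "C"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, island_fixture):
        m = pairwise_matrix(island_fixture, "Gst").to_numpy()
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_pairwise_cell_equals_subdataset_estimate(self, island_fixture):
        m = pairwise_matrix(island_fixture, "Dest")
        a, b = island_fixture.pop_names[:2]
        idx = np.concatenate(
            [island_fixture.pop_indices(a), island_fixture.pop_indices(b)]
        )
        sub = island_fixture.subset(idx)
        assert m.loc[a, b] == differentiation(sub).multilocus["Dest"]


class TestResample:
    def test_permutation_p_floor_and_range(self):
        # large maximally differentiated pops: no permutation ties the split
        rows = [[1, 1, 3, 3]] * 10 + [[2, 2, 4, 4]] * 10
        ds = make_diploid(rows, ["A"] * 10 + ["B"] * 10)
        res = resample(ds, "Dest", "permutation", 99, seed=5)
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_data_p_not_small(self, identical_pops):
        res = resample(identical_pops, "Dest", "permutation", 99, seed=5)
        assert res.p_value >= 1 / 100

    def test_single_locus_jackknife_errors(self):
        ds = make_diploid([[1, 2], [2, 2], [1, 1], [1, 2]], ["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            resample(ds, "Dest", "jackknife_loci", 1, seed=0)

    def test_jackknife_and_bootstrap_shapes(self, island_fixture):
        jk = resample(island_fixture, "Dest", "jackknife_loci", 1, seed=1)
        assert jk.se is not None and jk.se >= 0
        assert jk.n_resamples == island_fixture.n_loci
        bs = resample(island_fixture, "Dest", "bootstrap_loci", 60, seed=1)
        assert bs.ci_low <= bs.observed <= bs.ci_high or bs.ci_low <= bs.ci_high

    def test_seed_reproducibility(self, island_fixture):
        a = resample(island_fixture, "Gst", "permutation", 49, seed=42)
        b = resample(island_fixture, "Gst", "permutation", 49, seed=42)
        assert np.array_equal(a.replicates, b.replicates)
        assert a.p_value == b.p_value
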