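import math
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from popstruct.amova import (
    amova_three_level,
    amova_two_level,
    f_prime_st,
    maximal_recode,
    permute_amova,
)
from popstruct.core import ValidationError
from popstruct.distance import genotype_distance
from popstruct.simulate import sim_island

from conftest import make_diploid

# ---------------------------------------------------------------------------
# independent oracle: classic ANOVA on embedded coordinates.  For points in
# Euclidean space with d2 = squared Euclidean distance, the distance-based
# sums of squares equal the coordinate sums of squared deviations, so the
# oracle never touches the distance-matrix code path.


def anova_ss(points, labels):
    points = np.asarray(points, dtype=float)
    groups = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)
    ss_total = np.sum((points - points.mean(axis=0)) ** 2)
    ss_within = sum(
        np.sum((points[ix] - points[ix].mean(axis=0)) ** 2)
        for ix in map(np.asarray, groups.values())
    )
    return ss_total, ss_within, ss_total - ss_within


def oracle_two_level(points, labels):
    ss_total, ss_within, ss_among = anova_ss(points, labels)
    n = len(labels)
    sizes = np.array([labels.count(g) for g in dict.fromkeys(labels)], float)
    k = sizes.size
    ms_a, ms_w = ss_among / (k - 1), ss_within / (n - k)
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    s2a = (ms_a - ms_w) / n0
    return ss_total, ss_within, s2a / (s2a + ms_w)


class TestTwoLevel:
    def test_cross_pop_distance_only(self):
        d2 = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                d2[i, j] = d2[j, i] = 4.0
        res = amova_two_level(d2, ["A", "A", "B", "B"])
        assert res.table.set_index("stratum").SS["within_pops"] == 0.0
        assert res.phi["Phi_pt"] == pytest.approx(1.0)

    def test_zero_matrix_guarded_phi(self):
        res = amova_two_level(np.zeros((6, 6)), ["A"] * 3 + ["B"] * 3)
        assert res.phi["Phi_pt"] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_coordinate_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 9)
        points = rng.normal(size=(n, 3))
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        d2 = cdist(points, points, "sqeuclidean")
        d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        res = amova_two_level(d2, labels)
        ss_t, ss_w, phi = oracle_two_level(points, labels)
        tab = res.table.set_index("stratum")
        assert tab.SS["total"] == pytest.approx(ss_t, abs=1e-9)
        assert tab.SS["within_pops"] == pytest.approx(ss_w, abs=1e-9)
        assert res.phi["Phi_pt"] == pytest.approx(phi, abs=1e-9)

    def test_additivity_of_ss_and_df(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d2 = cdist(pts, pts, "sqeuclidean")
        np.fill_diagonal(d2, 0)
        res = amova_two_level((d2 + d2.T) / 2, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        tab = res.table.set_index("stratum")
        assert tab.SS["among_pops"] + tab.SS["within_pops"] == pytest.approx(
            tab.SS["total"], abs=1e-9
        )
        assert tab.df["among_pops"] + tab.df["within_pops"] == tab.df["total"]


class TestThreeLevel:
    @staticmethod
    def _design(rng, n_per_pop=(3, 2, 3, 4)):
        pops = [f"P{i+1}" for i, s in enumerate(n_per_pop) for _ in range(s)]
        regions = {"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"}
        pts = rng.normal(size=(len(pops), 2))
        d2 = cdist(pts, pts, "sqeuclidean")
        np.fill_diagonal(d2, 0)
        return (d2 + d2.T) / 2, pts, pops, regions

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_ss_match_coordinate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d2, pts, pops, regions = self._design(rng)
        res = amova_three_level(d2, pops, regions)
        tab = res.table.set_index("stratum")
        ss_total, ss_wp, _ = anova_ss(pts, pops)
        _, ss_wr, ss_ar = anova_ss(pts, [regions[p] for p in pops])
        assert tab.SS["total"] == pytest.approx(ss_total, abs=1e-9)
        assert tab.SS["within_pops"] == pytest.approx(ss_wp, abs=1e-9)
        assert tab.SS["among_regions"] == pytest.approx(ss_ar, abs=1e-9)
        assert tab.SS["among_pops_within_regions"] == pytest.approx(
            ss_wr - ss_wp, abs=1e-9
        )
        assert tab.df.drop("total").sum() == tab.df["total"]

    def test_identical_regions_no_region_signal(self):
        block = [[1, 1, 2, 3], [1, 2, 3, 3], [2, 2, 2, 2], [1, 1, 3, 3]]
        ds = make_diploid(
            block * 4,
            ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4,
            regions={"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"},
        )
        res = amova_three_level(genotype_distance(ds), ds.pops, ds.regions)
        assert res.phi["Phi_rt"] == pytest.approx(0.0, abs=1e-9)

    def test_maximally_distinct_regions(self):
        rows = [[1, 1]] * 4 + [[1, 1]] * 4 + [[2, 2]] * 4 + [[2, 2]] * 4
        ds = make_diploid(
            rows,
            ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4,
            regions={"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"},
        )
        res = amova_three_level(genotype_distance(ds), ds.pops, ds.regions)
        assert res.phi["Phi_rt"] == pytest.approx(1.0)
        assert res.phi["Phi_pt"] == pytest.approx(1.0)
        assert res.phi["Phi_pr"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_one_pop_per_region(self):
        d2 = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValidationError, match="Phi_pr"):
            amova_three_level(
                d2, ["P1", "P1", "P2", "P2"], {"P1": "R1", "P2": "R2"}
            )


class TestPermutation:
    def test_maximal_structure_hits_p_floor(self):
        rows = [[1, 1, 3, 3]] * 8 + [[2, 2, 4, 4]] * 8
        ds = make_diploid(rows, ["A"] * 8 + ["B"] * 8)
        res = permute_amova(genotype_distance(ds), ds.pops, m=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # N = 6 in two pops of 3: only C(6,3) = 20 label splits exist
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(6, 2))
        d2 = cdist(pts, pts, "sqeuclidean")
        np.fill_diagonal(d2, 0)
        d2 = (d2 + d2.T) / 2
        labels = ["A", "A", "A", "B", "B", "B"]
        obs = amova_two_level(d2, labels).phi["Phi_pt"]
        phis = []
        for a_idx in combinations(range(6), 3):
            lab = ["B"] * 6
            for i in a_idx:
                lab[i] = "A"
            phis.append(amova_two_level(d2, lab).phi["Phi_pt"])
        exact_p = np.mean([p >= obs - 1e-12 for p in phis])
        mc = permute_amova(d2, labels, m=1999, seed=5)
        assert mc.p_value == pytest.approx(exact_p, abs=0.03)

    def test_m_must_be_positive(self):
        with pytest.raises(ValidationError):
            permute_amova(np.zeros((4, 4)), ["A", "A", "B", "B"], m=0)


class TestFPrimeSt:
    def test_already_maximal_gives_one(self, two_pops_fixed):
        res = f_prime_st(two_pops_fixed)
        assert res.f_prime_st == pytest.approx(1.0, abs=1e-9)

    def test_recoding_disjoint_and_reversible_structure(self, island_fixture):
        rec = maximal_recode(island_fixture)
        sets = []
        for pop in rec.pop_names:
            sub = rec.alleles[rec.pop_indices(pop)]
            sets.append(set(sub[sub != 0].ravel().tolist()))
        for a, b in combinations(sets, 2):
            assert not (a & b)
        # genotype structure inside each population is preserved
        for pop in rec.pop_names:
            orig = island_fixture.alleles[island_fixture.pop_indices(pop)]
            new = rec.alleles[rec.pop_indices(pop)]
            assert np.array_equal(orig == 0, new == 0)
            # heterozygosity pattern unchanged
            assert np.array_equal(
                orig[:, 0::2] == orig[:, 1::2], new[:, 0::2] == new[:, 1::2]
            )

    def test_standardization_inflates(self):
        for seed in range(6):
            ds = sim_island(seed=seed, k_pops=3, n_per_pop=10, L_loci=5,
                            fst=0.2, n_alleles=4)
            res = f_prime_st(ds)
            if not math.isnan(res.f_prime_st):
                assert res.f_prime_st >= res.phi_pt - 1e-9

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(1, 5, size=(60, 10)).tolist()
        ds = make_diploid(rows, ["A"] * 30 + ["B"] * 30)
        res = f_prime_st(ds)
        assert abs(res.f_prime_st) < 0.15
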