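import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist, squareform

from popstruct.core import ValidationError
from popstruct.distance import (
    codominant_distance,
    compare_pairwise_stats,
    gower_center,
    haploid_distance,
    mantel,
    pcoa,
)

from conftest import make_diploid, make_haploid


def sharing_oracle(g1, g2):
    """Allele-sharing enumeration for one locus: count shared allele copies.

    d2 = 2 * ploidy - 2 * (number of shared copies) adjusted for the
    homozygote/heterozygote geometry; implemented as the explicit case table.
    """
    a, b = sorted(g1), sorted(g2)
    if a == b:
        return 0
    sa, sb = set(a), set(b)
    homo_a, homo_b = a[0] == a[1], b[0] == b[1]
    shared = len(sa & sb)
    if homo_a and homo_b:
        return 4  # ii vs jj
    if homo_a != homo_b:
        if shared == 1:
            return 1  # ii vs ij
        return 3      # ii vs jk
    # both heterozygous, not identical
    if shared == 1:
        return 1      # ij vs ik
    if shared == 0:
        return 2      # ij vs kl
    return 0


class TestCodominantDistance:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ((1, 1), (1, 1), 0),
            ((1, 2), (1, 2), 0),
            ((1, 1), (1, 2), 1),
            ((1, 2), (1, 3), 1),
            ((1, 1), (2, 2), 4),
            ((1, 1), (2, 3), 3),
            ((1, 2), (3, 4), 2),
        ],
    )
    def test_seven_case_table(self, g1, g2, expected):
        ds = make_diploid([list(g1), list(g2)], ["A", "A"])
        assert codominant_distance(ds).d2[0, 1] == expected
        assert sharing_oracle(g1, g2) == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_every_pair_matches_sharing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(1, 5, size=(10, 6)).tolist()
        ds = make_diploid(rows, ["A"] * 10)
        d2 = codominant_distance(ds).d2
        for i, j in itertools.combinations(range(10), 2):
            expected = sum(
                sharing_oracle(tuple(rows[i][2 * l : 2 * l + 2]),
                               tuple(rows[j][2 * l : 2 * l + 2]))
                for l in range(3)
            )
            assert d2[i, j] == pytest.approx(expected)

    def test_missing_locus_rescaled(self):
        rows = [[1, 1, 2, 2], [2, 2, 0, 0]]
        ds = make_diploid(rows, ["A", "A"])
        # shared loci: 1 of 2; raw d2 at L1 = 4, rescaled by 2/1
        assert codominant_distance(ds).d2[0, 1] == pytest.approx(8.0)

    def test_no_shared_locus_errors(self):
        rows = [[1, 1, 0, 0], [0, 0, 2, 2]]
        ds = make_diploid(rows, ["A", "A"])
        with pytest.raises(ValidationError, match="share no typed locus"):
            codominant_distance(ds)


class TestOtherMetrics:
    def test_haploid_mismatch_count(self):
        ds = make_haploid([[1, 2, 3], [1, 5, 6]], ["A", "A"])
        assert haploid_distance(ds).d2[0, 1] == 2

    def test_binary_mismatch(self):
        from popstruct.core import DataType, GenotypeDataset, LocusInfo
        from popstruct.distance import binary_distance

        ds = GenotypeDataset(
            sample_ids=["S1", "S2"], data_type=DataType.BINARY,
            loci=[LocusInfo(f"L{i}") for i in range(3)],
            alleles=np.array([[1, 0, 1], [0, 1, 1]]), pops=["A", "A"],
        ).validate()
        assert binary_distance(ds).d2[0, 1] == 2

    def test_haploid_missing_excluded_pairwise(self):
        ds = make_haploid([[1, 2, 0], [1, 3, 4]], ["A", "A"])
        # one mismatch over two shared loci, rescaled by 3/2
        assert haploid_distance(ds).d2[0, 1] == pytest.approx(1.5)


class TestGowerPcoa:
    def test_zero_matrix_centered_zero(self):
        assert np.allclose(gower_center(np.zeros((4, 4))), 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_row_sums_vanish(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(7, 3))
        d2 = cdist(pts, pts, "sqeuclidean")
        c = gower_center(d2)
        assert np.allclose(c.sum(axis=1), 0.0, atol=1e-9)

    def test_line_points_recover_gram_matrix(self):
        x = np.array([0.0, 1.0, 3.0])
        d2 = (x[:, None] - x[None, :]) ** 2
        c = gower_center(d2)
        xc = x - x.mean()
        assert np.allclose(c, np.outer(xc, xc), atol=1e-12)

    def test_pcoa_reconstructs_planar_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 2))
        d2 = cdist(pts, pts, "sqeuclidean")
        from popstruct.core import DistanceMatrix

        res = pcoa(DistanceMatrix([f"S{i}" for i in range(5)], (d2 + d2.T) / 2))
        rec = cdist(res.coordinates, res.coordinates, "sqeuclidean")
        assert np.allclose(rec, d2, atol=1e-8)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_identical_individuals_identical_coordinates(self):
        ds = make_diploid([[1, 2, 3, 3], [1, 2, 3, 3], [2, 2, 4, 4]], ["A"] * 3)
        res = pcoa(codominant_distance(ds))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_axes_orthogonal(self, island_fixture):
        from popstruct.distance import genotype_distance

        res = pcoa(genotype_distance(island_fixture))
        gram = res.coordinates.T @ res.coordinates
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6


class TestMantel:
    @staticmethod
    def _random_d2(rng, n):
        pts = rng.normal(size=(n, 2))
        d2 = cdist(pts, pts, "sqeuclidean")
        np.fill_diagonal(d2, 0)
        return (d2 + d2.T) / 2

    def test_self_correlation_is_one(self):
        a = self._random_d2(np.random.default_rng(0), 6)
        assert mantel(a, a, m=0).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = self._random_d2(np.random.default_rng(1), 6)
        assert mantel(a, 2 * a + 3, m=0).r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        a = self._random_d2(np.random.default_rng(1), 5)
        b = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValidationError, match="constant"):
            mantel(a, b, m=0)

    def test_monte_carlo_matches_exhaustive(self):
        rng = np.random.default_rng(4)
        a = self._random_d2(rng, 5)
        b = self._random_d2(rng, 5)
        obs = mantel(a, b, m=0).r
        ta = squareform(a, checks=False)
        rs = []
        for perm in itertools.permutations(range(5)):
            bp = b[np.ix_(perm, perm)]
            rs.append(np.corrcoef(ta, squareform(bp, checks=False))[0, 1])
        exact_p = np.mean([r >= obs - 1e-12 for r in rs])
        mc = mantel(a, b, m=1999, seed=9)
        assert mc.p_value == pytest.approx(exact_p, abs=0.03)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        a, b = self._random_d2(rng, 7), self._random_d2(rng, 7)
        p1 = mantel(a, b, m=99, seed=3).p_value
        p2 = mantel(a, b, m=99, seed=3).p_value
        assert p1 == p2


class TestComparePairwise:
    def test_island_fixture_statistics_agree(self, island_fixture):
        r_tab, p_tab, results = compare_pairwise_stats(
            island_fixture, ["Dest", "Gpprime_st", "Gst"], m=99, seed=2
        )
        assert np.allclose(np.diag(r_tab.to_numpy()), 1.0)
        assert np.allclose(r_tab.to_numpy(), r_tab.to_numpy().T, equal_nan=True)
        # both standardized estimators are monotone in differentiation
        assert r_tab.loc["Dest", "Gpprime_st"] > 0.9
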