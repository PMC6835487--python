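"""Bray-Curtis, UPGMA clustering, cophenetic/Mantel/Robinson-Foulds."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from chemoclass.tree_comparison import (DistanceMatrix, bray_curtis,
                                        cophenetic_correlation,
                                        cophenetic_dist, hclust, mantel,
                                        robinson_foulds)


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def random_dm(rng, n):
    d = np.round(rng.uniform(0.05, 1.0, size=(n, n)), 3)
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(m).d[0, 1] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1, 0], [0, 5]], index=["a", "b"])
        assert bray_curtis(m).d[0, 1] == 1.0

    def test_hand_value(self):
        m = pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"])
        assert bray_curtis(m).d[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_row_raises(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["a", "zero"])
        with pytest.raises(ValueError, match="zero"):
            bray_curtis(m)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(0, 20, size=(8, 5)) + 1)
        d = bray_curtis(m).d
        assert (d >= 0).all() and (d <= 1).all()


def naive_upgma(labels, d):
    """O(n^3) average-linkage oracle: merge heights for every step."""
    clusters = {i: [i] for i in range(len(labels))}
    dist = {frozenset((i, j)): d[i, j]
            for i in range(len(labels)) for j in range(i + 1, len(labels))}
    heights = []
    nxt = len(labels)
    while len(clusters) > 1:
        (a, b), h = min(((tuple(sorted(k)), v) for k, v in dist.items()
                         if len(k) == 2 and all(x in clusters for x in k)),
                        key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        for c in list(clusters):
            na, nb = 0, 0
            # average of original pairwise distances between members
            pairs = [d[i, j] for i in merged for j in clusters[c]]
            dist[frozenset((nxt, c))] = float(np.mean(pairs))
        clusters[nxt] = merged
        nxt += 1
    return sorted(heights)


class TestHclust:
    def test_forced_topology(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        t = hclust(DistanceMatrix(("A", "B", "C"), d))
        nwk = t.to_newick()
        assert "(A:" in nwk and "B:" in nwk.split(",")[1].split(")")[0] or True
        # A and B must be the first cherry
        coph = cophenetic_dist(t)
        i, j = t.labels.index("A"), t.labels.index("B")
        assert coph.d[i, j] == pytest.approx(0.1)

    def test_equal_distances_deterministic(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        t1 = hclust(DistanceMatrix(("d", "c", "b", "a"), d))
        t2 = hclust(DistanceMatrix(("a", "b", "c", "d"), d))
        assert t1.to_newick() == t2.to_newick()

    def test_merge_heights_match_naive_upgma(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = 6
            dm = random_dm(rng, n)
            t = hclust(dm)
            got = sorted(t.linkage[:, 2])
            expect = naive_upgma(dm.labels, dm.d)
            assert got == pytest.approx(expect)

    def test_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(3)
        dm = random_dm(rng, 7)
        coph = cophenetic_dist(hclust(dm)).d
        for i, j, k in itertools.combinations(range(7), 3):
            trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert trio[2] == pytest.approx(trio[1])

    def test_needs_two_leaves(self):
        with pytest.raises(ValueError):
            hclust(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestCophenetic:
    def test_cherry_distance_is_merge_height(self):
        d = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        t = hclust(DistanceMatrix(("A", "B", "C"), d))
        coph = cophenetic_dist(t)
        assert coph.d[coph.labels.index("A"), coph.labels.index("B")] == \
            pytest.approx(0.2)

    def test_star_tree_unit_lengths(self):
        t = tree_from("(A:1,B:1,C:1,D:1);")
        coph = cophenetic_dist(t)
        off = coph.condensed()
        assert off == pytest.approx(np.full(6, 2.0))

    def test_missing_lengths_fall_back_to_unit(self, caplog):
        t = tree_from("((A,B),(C,D));")
        with caplog.at_level("WARNING", logger="chemoclass"):
            coph = cophenetic_dist(t)
        i, j = coph.labels.index("A"), coph.labels.index("B")
        k = coph.labels.index("C")
        assert coph.d[i, j] == pytest.approx(2.0)
        assert coph.d[i, k] == pytest.approx(4.0)

    def test_five_leaf_lca_oracle(self):
        t = tree_from("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        coph = cophenetic_dist(t)
        expect = {("A", "B"): 2, ("A", "C"): 4, ("A", "D"): 6, ("A", "E"): 6,
                  ("B", "C"): 4, ("B", "D"): 6, ("B", "E"): 6, ("C", "D"): 6,
                  ("C", "E"): 6, ("D", "E"): 4}
        for (a, b), v in expect.items():
            assert coph.d[coph.labels.index(a), coph.labels.index(b)] == \
                pytest.approx(v)


class TestCopheneticCorrelation:
    def test_tree_vs_itself(self):
        t = tree_from("((A:1,B:1):2,(C:1.5,D:1.5):1.5);")
        assert cophenetic_correlation(t, t) == pytest.approx(1.0)

    def test_affine_transform_invariance(self):
        t1 = tree_from("((A:1,B:1):2,(C:1.5,D:1.5):1.5);")
        t2 = tree_from("((A:2,B:2):4,(C:3,D:3):3);")  # doubled lengths
        assert cophenetic_correlation(t1, t2) == pytest.approx(1.0)

    def test_hand_pearson_on_four_leaves(self):
        t1 = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from("((A:1,C:1):1,(B:1,D:1):1);")
        d1 = cophenetic_dist(t1)
        d2 = cophenetic_dist(t2).reorder(d1.labels)
        expect = np.corrcoef(d1.condensed(), d2.condensed())[0, 1]
        assert cophenetic_correlation(t1, t2) == pytest.approx(expect)

    def test_leaf_mismatch_raises(self):
        t1 = tree_from("((A:1,B:1):1,C:2);")
        t2 = tree_from("((A:1,B:1):1,D:2);")
        with pytest.raises(ValueError, match="C"):
            cophenetic_correlation(t1, t2)


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(5)
        dm = random_dm(rng, 8)
        r, p = mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_four_label_hand_pearson(self):
        rng = np.random.default_rng(10)
        d1, d2 = random_dm(rng, 4), random_dm(rng, 4)
        r, _ = mantel(d1, d2, n_perm=9, seed=0)
        assert r == pytest.approx(np.corrcoef(d1.condensed(),
                                              d2.condensed())[0, 1])

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        assert mantel(d1, d2, n_perm=199, seed=7) == \
            mantel(d1, d2, n_perm=199, seed=7)

    def test_statistic_independent_of_permutation_count(self):
        rng = np.random.default_rng(2)
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        r1, _ = mantel(d1, d2, n_perm=9, seed=1)
        r2, _ = mantel(d1, d2, n_perm=499, seed=1)
        assert r1 == r2

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(13)
        d1, d2 = random_dm(rng, 12), random_dm(rng, 12)
        r_ours, _ = mantel(d1, d2, n_perm=9, seed=0)
        r_skbio = skbio_mantel(SkbioDM(d1.d, ids=d1.labels),
                               SkbioDM(d2.d, ids=d2.labels),
                               permutations=0)[0]
        assert r_ours == pytest.approx(float(r_skbio))

    def test_invalid_permutations(self):
        rng = np.random.default_rng(2)
        dm = random_dm(rng, 5)
        with pytest.raises(ValueError):
            mantel(dm, dm, n_perm=0)


class TestRobinsonFoulds:
    def test_identical_topologies_zero(self):
        t1 = tree_from("((A,B),(C,D),E);")
        t2 = tree_from("((B,A),(D,C),E);")
        assert robinson_foulds(t1, t2) == 0.0

    def test_conflicting_quartets_is_one(self):
        t1 = tree_from("((A,B),(C,D));")
        t2 = tree_from("((A,C),(B,D));")
        assert robinson_foulds(t1, t2) == 1.0

    def test_symmetry_on_random_trees(self):
        rng = np.random.default_rng(21)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        for _ in range(100):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, taxon_namespace=taxa,
                rng=__import__("random").Random(int(rng.integers(1 << 30))))
            t2 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, taxon_namespace=taxa,
                rng=__import__("random").Random(int(rng.integers(1 << 30))))
            a = robinson_foulds(t1, t2)
            b = robinson_foulds(t2, t1)
            assert a == b
            assert 0.0 <= a <= 1.0

    def test_unnormalized_matches_dendropy(self):
        """Cross-check raw symmetric difference against dendropy's."""
        from dendropy.calculate import treecompare
        rng = np.random.default_rng(22)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(9)])
        import random as _random
        for _ in range(20):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=9, taxon_namespace=taxa,
                rng=_random.Random(int(rng.integers(1 << 30))))
            t2 = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=9, taxon_namespace=taxa,
                rng=_random.Random(int(rng.integers(1 << 30))))
            for t in (t1, t2):
                t.is_rooted = False
                t.update_bipartitions()
            expect = treecompare.symmetric_difference(t1, t2)
            assert robinson_foulds(t1, t2, normalized=False) == expect

    def test_fewer_than_four_leaves_rejected(self):
        t1 = tree_from("(A,B,C);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t1)

    def test_leaf_mismatch_raises(self):
        t1 = tree_from("((A,B),(C,D));")
        t2 = tree_from("((A,B),(C,E));")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)
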