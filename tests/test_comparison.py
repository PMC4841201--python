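import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from tudscan import comparison as cmp
from tudscan import kmer_core as kc
from tudscan.sequence_io import Genome, ValidationError

from conftest import random_binary_tree, random_seq, tree_splits


def vectors_from_random_genomes(rng, n, length=3000, k=4):
    genomes = [Genome(f"g{i}", random_seq(rng, length)) for i in range(n)]
    vs = [kc.canonicalize(kc.usage_deviation(g, k)) for g in genomes]
    return kc.filter_universal(vs)


def additive_matrix(tree: TreeNode) -> DistanceMatrix:
    """Independent oracle: leaf-to-leaf path-length sums on a known tree."""
    tt = tree.tip_tip_distances()
    return DistanceMatrix(tt.data, ids=list(tt.ids))


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self, rng):
        x, y = vectors_from_random_genomes(rng, 2)
        assert cmp.euclidean_distance(x, x) == 0.0
        ymod = dict(y.deviation)
        w0, w1 = y.words[0], y.words[1]
        ymod[w0] = x.deviation[w0] + 3.0
        ymod[w1] = x.deviation[w1] + 4.0
        for w in y.words[2:]:
            ymod[w] = x.deviation[w]
        from dataclasses import replace

        y345 = replace(y, deviation=ymod)
        assert cmp.euclidean_distance(x, y345) == pytest.approx(5.0)

    def test_triangle_inequality(self, rng):
        a, b, c = vectors_from_random_genomes(rng, 3)
        dab = cmp.euclidean_distance(a, b)
        dbc = cmp.euclidean_distance(b, c)
        dac = cmp.euclidean_distance(a, c)
        assert dac <= dab + dbc + 1e-12

    def test_mismatched_word_lists_rejected(self, rng):
        x, _ = vectors_from_random_genomes(rng, 2)
        y = kc.usage_deviation(Genome("h", random_seq(rng, 3000)), 4)
        with pytest.raises(ValidationError):
            cmp.euclidean_distance(x, y)


class TestDistanceMatrix:
    def test_matches_pairwise_oracle(self, rng):
        vs = vectors_from_random_genomes(rng, 4)
        dm = cmp.distance_matrix(vs)
        for i, x in enumerate(vs):
            for j, y in enumerate(vs):
                assert dm.data[i, j] == pytest.approx(cmp.euclidean_distance(x, y))

    def test_duplicate_genome_has_zero_distance(self, rng):
        seq = random_seq(rng, 3000)
        vs = [kc.usage_deviation(Genome(n, seq), 4) for n in ("a", "b")]
        dm = cmp.distance_matrix(kc.filter_universal(vs))
        assert dm.data[0, 1] == 0.0

    def test_permutation_invariance(self, rng):
        vs = vectors_from_random_genomes(rng, 4)
        dm = cmp.distance_matrix(vs)
        perm = [2, 0, 3, 1]
        dm2 = cmp.distance_matrix([vs[i] for i in perm])
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert dm2.data[a, b] == dm.data[i, j]

    def test_fewer_than_two_rejected(self, rng):
        (v,) = vectors_from_random_genomes(rng, 2)[:1]
        with pytest.raises(ValidationError):
            cmp.distance_matrix([v])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float), ids=["a", "b", "c"]
        )
        tree = cmp.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # b_a = (d_ab + d_ac - d_bc) / 2, etc.
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_recovers_four_taxon_tree_exactly(self):
        # tree ((a:2,b:3):1,(c:4,d:5)) via path sums
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        dm = DistanceMatrix(D, ids=list("abcd"))
        tree = cmp.neighbor_joining(dm)
        assert tree_splits(tree) == {
            frozenset([frozenset("ab"), frozenset("cd")])
        }
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 4.0, "d": 5.0})
        internal = [
            n.length for n in tree.postorder(include_self=False) if not n.is_tip()
        ]
        assert internal == pytest.approx([1.0])

    @pytest.mark.parametrize("seed", range(15))
    def test_consistency_on_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        true_tree = random_binary_tree(rng, n)
        tree = cmp.neighbor_joining(additive_matrix(true_tree))
        assert tree_splits(tree) == tree_splits(true_tree)

    def test_agrees_with_reference_nj_on_noisy_matrix(self, rng):
        vs = vectors_from_random_genomes(rng, 6)
        dm = cmp.distance_matrix(vs)
        ours = cmp.neighbor_joining(dm)
        ref = skbio_nj(dm)
        assert tree_splits(ours) == tree_splits(ref)

    def test_requires_three_taxa(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["a", "b"])
        with pytest.raises(ValidationError):
            cmp.neighbor_joining(dm)


class TestAverageLinkage:
    def test_two_leaves_merge_at_half_distance(self):
        dm = DistanceMatrix(np.array([[0, 3], [3, 0]], float), ids=["a", "b"])
        tree = cmp.average_linkage(dm)
        assert {t.name: t.length for t in tree.tips()} == {"a": 1.5, "b": 1.5}

    def test_ultrametric_matrix_is_a_fixed_point(self, rng):
        # a matrix that is exactly ultrametric: cophenetic distances of an
        # average-linkage tree built (by scipy) from random data
        X = rng.random((7, 5))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        coph = squareform(cophenet(scipy_average(squareform(D))))
        ids = [f"t{i}" for i in range(7)]
        tree = cmp.average_linkage(DistanceMatrix(coph, ids=ids))
        tt = tree.tip_tip_distances(); order = [ids.index(i) for i in tt.ids]
        np.testing.assert_allclose(tt.data, coph[np.ix_(order, order)], atol=1e-9)

    def test_cophenetic_agrees_with_scipy_on_generic_matrix(self, rng):
        vs = vectors_from_random_genomes(rng, 6)
        dm = cmp.distance_matrix(vs)
        tree = cmp.average_linkage(dm)
        Z = scipy_average(squareform(dm.data))
        coph = squareform(cophenet(Z))
        ids = list(dm.ids)
        tt = tree.tip_tip_distances(); order = [ids.index(i) for i in tt.ids]
        np.testing.assert_allclose(tt.data, coph[np.ix_(order, order)], atol=1e-9)

    def test_merge_heights_non_decreasing(self, rng):
        vs = vectors_from_random_genomes(rng, 6)
        tree = cmp.average_linkage(cmp.distance_matrix(vs))
        def height(node):
            if node.is_tip():
                return 0.0
            child = node.children[0]
            return height(child) + child.length
        for node in tree.postorder():
            if not node.is_tip():
                for child in node.children:
                    assert height(node) >= height(child) - 1e-12

    def test_requires_two_taxa(self):
        with pytest.raises(ValidationError):
            cmp.average_linkage(DistanceMatrix(np.zeros((1, 1)), ids=["a"]))


class TestPCA:
    def test_reconstruction_of_centered_data(self, rng):
        vs = vectors_from_random_genomes(rng, 6)
        res = cmp.pca(vs)
        X = np.log(np.vstack([v.deviation_array() for v in vs]))
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(res.scores @ res.loadings.T, Xc, atol=1e-9)

    def test_variance_fractions_sum_to_one_and_non_increasing(self, rng):
        res = cmp.pca(vectors_from_random_genomes(rng, 6))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_identical_genomes_get_identical_scores(self, rng):
        seq = random_seq(rng, 3000)
        genomes = [Genome(n, seq) for n in ("a", "b")] + [
            Genome("c", random_seq(rng, 3000))
        ]
        vs = kc.filter_universal(
            [kc.canonicalize(kc.usage_deviation(g, 4)) for g in genomes]
        )
        res = cmp.pca(vs)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-9)

    def test_zero_deviation_with_log_rejected(self, rng):
        vs = [kc.usage_deviation(Genome("a", "ACGC" * 500), 4),
              kc.usage_deviation(Genome("b", random_seq(rng, 2000)), 4)]
        with pytest.raises(ValidationError, match="filter_universal"):
            cmp.pca(vs)

    def test_no_log_skips_positivity_requirement(self, rng):
        vs = [kc.usage_deviation(Genome("a", "ACGC" * 500), 4),
              kc.usage_deviation(Genome("b", random_seq(rng, 2000)), 4)]
        res = cmp.pca(vs, log_transform=False)
        assert res.scores.shape[0] == 2


def brute_force_monophyly(tree: TreeNode, labels: dict[str, str]) -> dict[str, bool]:
    """Independent oracle: sever every edge of the unrooted tree graph and
    test whether some severed edge isolates exactly one group."""
    adj: dict[int, set[int]] = {}
    names: dict[int, str] = {}
    index = {id(n): i for i, n in enumerate(tree.traverse(include_self=True))}
    for node in tree.traverse(include_self=True):
        i = index[id(node)]
        adj.setdefault(i, set())
        if node.is_tip():
            names[i] = node.name
        for child in node.children:
            j = index[id(child)]
            adj[i].add(j)
            adj.setdefault(j, set()).add(i)
    edges = {tuple(sorted((a, b))) for a in adj for b in adj[a]}
    groups = sorted(set(labels.values()))
    sides = []
    for a, b in edges:
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((a, b), (b, a)) or y in seen:
                    continue
                seen.add(y)
                stack.append(y)
        sides.append(frozenset(names[i] for i in seen if i in names))
    all_tips = frozenset(names.values())
    result = {}
    for g in groups:
        members = frozenset(n for n in all_tips if labels[n] == g)
        result[g] = any(s == members or all_tips - s == members for s in sides)
    return result


class TestMonophyly:
    def test_clean_split_is_monophyletic(self):
        tree = TreeNode.read(["((a1:1,a2:1):1,(b1:1,b2:1):1);"])
        labels = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        assert cmp.monophyly_check(tree, labels) == {"a": True, "b": True}

    def test_interleaved_groups_are_not(self):
        tree = TreeNode.read(["((a1:1,b1:1):1,(a2:1,b2:1):1);"])
        labels = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        assert cmp.monophyly_check(tree, labels) == {"a": False, "b": False}

    def test_unlabeled_leaf_rejected(self):
        tree = TreeNode.read(["((a1:1,a2:1):1,b1:1);"])
        with pytest.raises(ValidationError):
            cmp.monophyly_check(tree, {"a1": "a", "a2": "a"})

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_edge_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(rng, 20)
        tips = [t.name for t in tree.tips()]
        labels = {t: f"grp{rng.integers(0, 4)}" for t in tips}
        assert cmp.monophyly_check(tree, labels) == brute_force_monophyly(tree, labels)
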