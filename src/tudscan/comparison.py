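"""Between-genome comparison: distances, trees and ordination.

Usage-deviation vectors are compared by Euclidean distance over a shared
word list. The resulting matrix feeds two tree builders — neighbor joining
(Saitou & Nei, producing an unrooted tree that is exact on tree-additive
matrices) and UPGMA average-linkage (producing a rooted ultrametric
dendrogram) — and a PCA on log-transformed deviations.

Trees are :class:`skbio.TreeNode` objects and distance matrices
:class:`skbio.DistanceMatrix`, so they serialize to Newick/TSV and
interoperate with the wider ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .kmer_core import UsageVector
from .sequence_io import ValidationError


def euclidean_distance(x: UsageVector, y: UsageVector) -> float:
    """Euclidean distance between two deviation vectors sharing a word list."""
    if x.words != y.words:
        raise ValidationError(
            f"word lists differ between {x.source_id!r} and {y.source_id!r}; "
            "canonicalize/filter the collection together before comparing"
        )
    return float(np.linalg.norm(x.deviation_array() - y.deviation_array()))


def distance_matrix(vectors: list[UsageVector]) -> DistanceMatrix:
    """All-pairs Euclidean distance matrix, labels in input order."""
    if len(vectors) < 2:
        raise ValidationError("need at least 2 vectors for a distance matrix")
    words = vectors[0].words
    for v in vectors[1:]:
        if v.words != words:
            raise ValidationError("all vectors must share an identical word list")
    ids = [v.source_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate source ids in vector collection")
    X = np.vstack([v.deviation_array() for v in vectors])
    return DistanceMatrix(squareform(pdist(X, metric="euclidean")), ids=ids)


def matrix_from_table(X: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Distance matrix straight from a (genomes x words) deviation table."""
    return DistanceMatrix(squareform(pdist(np.asarray(X, dtype=float))), ids=ids)


def _clamped_pair(total: float, li: float, lj: float) -> tuple[float, float]:
    # negative branch estimate: clamp to 0, give the deficit to the sister
    # branch so the pair still sums to their joining distance
    if li < 0:
        return 0.0, total
    if lj < 0:
        return total, 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree (Saitou–Nei).

    Standard Q-matrix agglomeration with the usual branch-length formulas;
    on tree-additive input the generating topology and branch lengths are
    recovered exactly. Negative branch-length estimates are clamped to zero
    with the deficit moved to the sister branch. Deterministic given the
    input label order (ties resolved by the first minimal Q entry in row-major
    order). The returned tree has a trifurcating root, i.e. is unrooted.
    """
    if dm.shape[0] < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamped_pair(D[i, j], li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
    # resolve the final three branches by the three-point formulas
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return TreeNode(children=[a, b, c])


def average_linkage(dm: DistanceMatrix) -> TreeNode:
    """Rooted UPGMA dendrogram (unweighted average linkage).

    Merge heights are half the average inter-cluster distance and are
    non-decreasing; on an exactly ultrametric matrix the tree's cophenetic
    (tip-to-tip path) distances reproduce the input. Ties are broken by the
    lexicographically smallest pair of cluster labels, a cluster being
    labeled by its smallest member id, so results are platform-independent.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValidationError("average linkage requires at least 2 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    # cluster state: node, size, height, smallest member label
    clusters: dict[int, tuple[TreeNode, int, float, str]] = {
        i: (TreeNode(name=str(lab)), 1, 0.0, str(lab)) for i, lab in enumerate(dm.ids)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_key = n
    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            pair_labels = tuple(sorted((clusters[i][3], clusters[j][3])))
            key = (d, pair_labels)
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        d_ij = dist[(i, j)]
        node_i, size_i, h_i, lab_i = clusters[i]
        node_j, size_j, h_j, lab_j = clusters[j]
        height = d_ij / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        merged = TreeNode(children=[node_i, node_j])
        del clusters[i], clusters[j]
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), d in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(a, b)] = d
        for k in clusters:
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            d_mk = (size_i * d_ik + size_j * d_jk) / (size_i + size_j)
            new_dist[(min(k, next_key), max(k, next_key))] = d_mk
        clusters[next_key] = (merged, size_i + size_j, height, min(lab_i, lab_j))
        dist = new_dist
        next_key += 1
    (root, _, _, _) = next(iter(clusters.values()))
    return root


@dataclass
class PCAResult:
    """Scores, loadings and per-component variance fractions of a PCA."""

    ids: list[str]
    words: list[str]
    scores: np.ndarray  # genomes x components
    loadings: np.ndarray  # words x components
    variance_fraction: np.ndarray


def pca_from_matrix(
    X: np.ndarray, ids: list[str], words: list[str], log_transform: bool = True
) -> PCAResult:
    """PCA core on a (genomes x words) deviation table.

    Natural-log transform (optional), column centering, no column scaling,
    then SVD. Variance fractions come from the squared singular values.
    Component signs are fixed so the largest-magnitude loading in each
    column is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 genomes")
    if log_transform:
        if (X <= 0).any():
            raise ValidationError(
                "log transform requires strictly positive deviations; "
                "apply filter_universal first to drop words absent from some genome"
            )
        X = np.log(X)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| per component made positive
    for comp in range(Vt.shape[0]):
        pivot = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, pivot] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    total = float((s**2).sum())
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        ids=list(ids),
        words=list(words),
        scores=U * s,
        loadings=Vt.T,
        variance_fraction=frac,
    )


def pca(vectors: list[UsageVector], log_transform: bool = True) -> PCAResult:
    """PCA of a collection of usage-deviation vectors (log-transformed by default)."""
    if len(vectors) < 2:
        raise ValidationError("PCA requires at least 2 vectors")
    words = vectors[0].words
    for v in vectors[1:]:
        if v.words != words:
            raise ValidationError("all vectors must share an identical word list")
    X = np.vstack([v.deviation_array() for v in vectors])
    return pca_from_matrix(X, [v.source_id for v in vectors], list(words), log_transform)


def _clade_sets(tree: TreeNode) -> set[frozenset[str]]:
    sets: set[frozenset[str]] = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            sets.add(frozenset([node.name]))
        else:
            sets.add(frozenset(t.name for t in node.tips()))
    return sets


def monophyly_check(tree: TreeNode, labels: dict[str, str]) -> dict[str, bool]:
    """For each group, is its leaf set separated from the rest by one edge?

    The tree is treated as unrooted: a group is monophyletic if some edge's
    bipartition puts exactly that group's leaves on one side — equivalently,
    if the group's leaf set (or its complement) appears as a clade of the
    rooted representation. Singleton and all-leaf groups are trivially
    monophyletic.
    """
    leaves = frozenset(t.name for t in tree.tips())
    missing = [name for name in leaves if name not in labels]
    if missing:
        raise ValidationError(f"unlabeled leaves: {sorted(missing)}")
    groups: dict[str, frozenset[str]] = {}
    for name in leaves:
        groups.setdefault(labels[name], set())
    for name in leaves:
        groups[labels[name]] = frozenset(groups[labels[name]] | {name})
    clades = _clade_sets(tree)
    result = {}
    for group, members in groups.items():
        result[group] = (
            len(members) == 1
            or members == leaves
            or members in clades
            or (leaves - members) in clades
        )
    return result
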