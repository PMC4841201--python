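"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skbio import TreeNode

from tudscan.sequence_io import StrandPair

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def naive_count_words(pair: StrandPair, k: int) -> dict[str, int]:
    """Brute-force per-position substring scan over both strands.

    Deliberately independent of the package's vectorized counter: walks each
    strand position by position and skips any window containing N.
    """
    counts: dict[str, int] = {}
    for strand in (pair.forward, pair.reverse):
        for i in range(len(strand) - k + 1):
            w = strand[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
    return counts


def random_seq(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, length)]
    if n_prob > 0:
        seq[rng.random(length) < n_prob] = "N"
    return "".join(seq)


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random binary tree with strictly positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.5, 2.0))
        b.length = float(rng.uniform(0.5, 2.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for x, n in enumerate(nodes) if x not in (i, j)] + [parent]
    return nodes[0]


def tree_splits(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of the (unrooted) tree, canonicalized."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset([side, other]))
    return splits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
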