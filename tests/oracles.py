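"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: set algebra by
explicit loops, chi-square by the textbook observed/expected sum, BH by the
hand-executed step-up rule, and tree constraint checks by exhaustive
enumeration of all binary polytomy resolutions.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np

# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

def core_by_loop(genomes, clusters, counts, genome_set):
    out = set()
    for j, c in enumerate(clusters):
        if all(counts[genomes.index(g)][j] >= 1 for g in genome_set):
            out.add(c)
    return out


def exclusive_by_loop(genomes, clusters, counts, in_group, out_group):
    out = set()
    for j, c in enumerate(clusters):
        ok_in = all(counts[genomes.index(g)][j] >= 1 for g in in_group)
        ok_out = all(counts[genomes.index(g)][j] == 0 for g in out_group)
        if ok_in and ok_out:
            out.add(c)
    return out


def single_copy_by_loop(genomes, clusters, counts, genome_set):
    out = set()
    for j, c in enumerate(clusters):
        if all(counts[genomes.index(g)][j] == 1 for g in genome_set):
            out.add(c)
    return out


# ---------------------------------------------------------------------------
# chi-square and BH
# ---------------------------------------------------------------------------

def chi_square_by_loop(per_group_counts: dict) -> float:
    """Textbook Pearson chi-square on the 2 x G (present/absent) table."""
    groups = sorted(per_group_counts)
    obs = []
    for g in groups:
        k, n = per_group_counts[g]
        obs.append([k, n - k])
    obs = np.array(obs, dtype=float).T  # rows present/absent, cols groups
    total = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if row[0] == 0 or row[1] == 0:
        return 0.0
    stat = 0.0
    for i in range(2):
        for j in range(len(groups)):
            e = row[i] * col[j] / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def bh_by_hand(pvals):
    """Step-up rule executed literally: q(i) = min_{j>=i} p(j)*m/j, clipped."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    for rank_idx in range(m):
        q_sorted[rank_idx] = min(
            min(pvals[order[j]] * m / (j + 1) for j in range(rank_idx, m)), 1.0
        )
    q = [0.0] * m
    for rank_idx, i in enumerate(order):
        q[i] = q_sorted[rank_idx]
    return q


# ---------------------------------------------------------------------------
# tree resolution enumeration
# ---------------------------------------------------------------------------
# trees are nested tuples: a leaf is a string, an internal node is a tuple of
# children. The root is the as-parsed seed node.

def from_dendropy(node):
    if node.is_leaf():
        return node.taxon.label
    return tuple(from_dendropy(c) for c in node.child_nodes())


def _join_shapes(k):
    """All rooted binary tree shapes over the atoms 0..k-1.

    Atoms are ints so grafting can never descend into an already-resolved
    child subtree.
    """
    if k == 1:
        yield 0
        return
    for shape in _join_shapes(k - 1):
        yield from _graft(shape, k - 1)


def _graft(shape, new):
    yield (shape, new)  # above the root of this subshape
    if isinstance(shape, tuple):
        a, b = shape
        for g in _graft(a, new):
            yield (g, b)
        for g in _graft(b, new):
            yield (a, g)


def _substitute(shape, items):
    if isinstance(shape, int):
        return items[shape]
    return tuple(_substitute(s, items) for s in shape)


def resolutions(tree):
    """All fully binary resolutions of a rooted (possibly multifurcating) tree."""
    if isinstance(tree, str):
        yield tree
        return
    child_res = [list(resolutions(c)) for c in tree]
    shapes = list(_join_shapes(len(tree)))
    for combo in itertools.product(*child_res):
        for shape in shapes:
            yield _substitute(shape, combo)


def clades(tree, acc=None):
    """All edge-delimited leaf sets: internal clades plus leaf singletons."""
    if acc is None:
        acc = []
    if isinstance(tree, str):
        s = frozenset([tree])
        acc.append(s)
        return s, acc
    leaves = frozenset()
    for c in tree:
        sub, _ = clades(c, acc)
        leaves |= sub
    acc.append(leaves)
    return leaves, acc


def leaf_set(tree):
    return clades(tree)[0]


def oracle_split_compatible(tree, taxa: Iterable[str]) -> bool:
    """Some binary resolution displays taxa | complement on an edge."""
    taxa = frozenset(taxa)
    all_leaves = leaf_set(tree)
    comp = all_leaves - taxa
    for res in resolutions(tree):
        _, cl = clades(res, [])
        sets = set(cl)
        if taxa in sets or comp in sets:
            return True
    return False


def oracle_joint_clades(tree, required: list[frozenset]) -> bool:
    """Some single binary resolution realizes every required leaf set as a clade."""
    all_leaves = leaf_set(tree)
    required = [frozenset(r) for r in required]
    for res in resolutions(tree):
        _, cl = clades(res, [])
        sets = set(cl) | {all_leaves}
        if all(r in sets for r in required):
            return True
    return False
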