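"""Screening gene trees for topologies that separate phenotype groups.

Sequence variants of shared (single-copy core) genes can track a phenotype:
if susceptibility groups correspond to clades in a gene tree, that gene's
variants covary with the phenotype. The screen tests each gene tree against
three constraint topologies:

``ALL_MONO``
    every phenotype group (resistant / nonpermissive / permissive) forms a
    monophyletic clade, relationships among clades unconstrained;
``R_SISTER_NP``
    as ``ALL_MONO``, and additionally the resistant clade is sister to the
    nonpermissive clade (their union is also a clade);
``P_NP_SPLIT``
    for trees spanning only the susceptible genomes: permissive and
    nonpermissive leaves fall on opposite sides of a single branch.

Polytomies are read permissively: a tree matches if SOME resolution of its
polytomies displays the required clades/split, so an unresolved tree never
contradicts a constraint it could be refined to satisfy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .pangenome import NONPERMISSIVE, PERMISSIVE, RESISTANT, GeneClusterMatrix, PhenotypeMap

__all__ = [
    "ALL_MONO",
    "R_SISTER_NP",
    "P_NP_SPLIT",
    "CONSTRAINTS",
    "TopologyConstraint",
    "LabeledGeneTree",
    "ScreenResult",
    "parse_labeled_tree",
    "split_compatible",
    "clade_compatible",
    "matches_constraint",
    "screen_trees",
    "screen_summary",
]

logger = logging.getLogger(__name__)

ALL_MONO = "ALL_MONO"
R_SISTER_NP = "R_SISTER_NP"
P_NP_SPLIT = "P_NP_SPLIT"


@dataclass(frozen=True)
class TopologyConstraint:
    """A named topological requirement over phenotype groups."""

    id: str
    groups: tuple[str, ...]  # groups that must be present among the leaves


CONSTRAINTS: dict[str, TopologyConstraint] = {
    ALL_MONO: TopologyConstraint(ALL_MONO, (RESISTANT, NONPERMISSIVE, PERMISSIVE)),
    R_SISTER_NP: TopologyConstraint(R_SISTER_NP, (RESISTANT, NONPERMISSIVE, PERMISSIVE)),
    P_NP_SPLIT: TopologyConstraint(P_NP_SPLIT, (PERMISSIVE, NONPERMISSIVE)),
}


@dataclass
class LabeledGeneTree:
    """A gene tree whose leaves are genomes with phenotype labels."""

    cluster_id: str
    tree: dendropy.Tree
    leaf_to_group: dict[str, str]

    @property
    def leaves(self) -> set[str]:
        return set(self.leaf_to_group)

    def group_leaves(self, group: str) -> set[str]:
        return {l for l, g in self.leaf_to_group.items() if g == group}

    @property
    def n_internal_edges(self) -> int:
        """Internal branches of the unrooted tree (0 for a star)."""
        root = self.tree.seed_node
        n = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is root or edge.tail_node is None:
                continue
            if not edge.head_node.is_leaf() and edge.tail_node is not root:
                n += 1
        # a bifurcating root subdivides one unrooted edge into two
        root_children = root.child_nodes()
        if len(root_children) == 2:
            internal_kids = sum(1 for c in root_children if not c.is_leaf())
            if internal_kids == 2:
                n += 1
        elif len(root_children) > 2:
            n += sum(1 for c in root_children if not c.is_leaf())
        return n


@dataclass
class ScreenResult:
    """Outcome of screening one gene tree."""

    cluster_id: str
    matched: str | None
    n_internal_edges: int
    functions: set[tuple[str, str]] = field(default_factory=set)


def parse_labeled_tree(newick: str, ph: PhenotypeMap, cluster_id: str = "") -> LabeledGeneTree:
    """Parse a Newick string and attach phenotype groups to its leaves.

    Polytomies and branch lengths are preserved as written; internal node
    labels (e.g. support values) are parsed and ignored by the screen.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"unparseable Newick: {exc}") from exc
    tree.is_rooted = True  # as-parsed orientation is meaningful to the screen
    leaf_to_group = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None:
            raise ValueError("tree contains an unnamed leaf")
        if name not in ph.assignments:
            raise KeyError(f"leaf {name!r} has no phenotype assignment")
        leaf_to_group[name] = ph.group(name)
    if len(leaf_to_group) < len(tree.leaf_nodes()):
        raise ValueError("duplicate leaf names in tree")
    return LabeledGeneTree(cluster_id=cluster_id, tree=tree, leaf_to_group=leaf_to_group)


def _adjacency(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Undirected adjacency over dendropy nodes, plus leaf-name -> node."""
    adj: dict = {}
    leaf_of: dict = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, set())
        for child in node.child_nodes():
            adj[node].add(child)
            adj.setdefault(child, set()).add(node)
        if node.is_leaf() and node.taxon is not None:
            leaf_of[node.taxon.label] = node
    return adj, leaf_of


def _steiner_vertices(adj: Mapping, keep_leaves: set) -> set:
    """Vertices of the minimal subtree connecting ``keep_leaves``.

    Obtained by repeatedly stripping degree-1 vertices that are not target
    leaves; what survives is the union of all paths between targets.
    """
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    alive = set(adj)
    queue = [v for v in adj if degree[v] <= 1 and v not in keep_leaves]
    while queue:
        v = queue.pop()
        if v not in alive or v in keep_leaves:
            continue
        alive.discard(v)
        for u in adj[v]:
            if u in alive:
                degree[u] -= 1
                if degree[u] <= 1 and u not in keep_leaves:
                    queue.append(u)
    return alive


def split_compatible(t: LabeledGeneTree, taxa: Iterable[str]) -> bool:
    """Can the tree be refined so that ``taxa | rest`` is displayed by an edge?

    True iff the minimal subtree connecting ``taxa`` and the minimal subtree
    connecting the complement share at most one vertex — then resolving that
    shared polytomy (if any) separates the two sides. Unrooted semantics:
    the result is the same for ``taxa`` and its complement.
    """
    taxa = set(taxa)
    if not taxa or not taxa < t.leaves:
        raise ValueError("taxa must be a nonempty proper subset of the leaves")
    adj, leaf_of = _adjacency(t.tree)
    side_a = {leaf_of[x] for x in taxa}
    side_b = {leaf_of[x] for x in t.leaves - taxa}
    sub_a = _steiner_vertices(adj, side_a)
    sub_b = _steiner_vertices(adj, side_b)
    return len(sub_a & sub_b) <= 1


def clade_compatible(t: LabeledGeneTree, taxa: Iterable[str]) -> bool:
    """Can ``taxa`` be made a clade of the ROOTED tree by resolving polytomies?

    True iff every child subtree of the most recent common ancestor of
    ``taxa`` is entirely inside or entirely outside ``taxa``: the in-side
    children of that polytomy can then be grouped under a new node. A group
    spanning all leaves is trivially a clade.
    """
    taxa = set(taxa)
    if not taxa or not taxa <= t.leaves:
        raise ValueError("taxa must be a nonempty subset of the leaves")
    if taxa == t.leaves:
        return True
    mrca = t.tree.mrca(taxa=[t.tree.taxon_namespace.get_taxon(x) for x in sorted(taxa)])
    for child in mrca.child_nodes():
        below = {l.taxon.label for l in child.leaf_iter()}
        if below & taxa and not below <= taxa:
            return False
    return True


def _reroot(t: LabeledGeneTree, rooting: str, outgroup: Iterable[str] | None) -> LabeledGeneTree:
    if rooting == "as-parsed":
        return t
    tree = t.tree.clone(depth=1)
    if rooting == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif rooting == "outgroup":
        if not outgroup:
            raise ValueError("outgroup rooting requires an outgroup leaf set")
        taxa = [tree.taxon_namespace.get_taxon(x) for x in sorted(set(outgroup))]
        mrca = tree.mrca(taxa=taxa)
        if mrca is not tree.seed_node:
            tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting mode {rooting!r}")
    return LabeledGeneTree(t.cluster_id, tree, dict(t.leaf_to_group))


def matches_constraint(
    t: LabeledGeneTree,
    c: TopologyConstraint | str,
    rooting: str = "as-parsed",
    outgroup: Iterable[str] | None = None,
) -> bool:
    """Does the tree (under some polytomy resolution) satisfy the constraint?"""
    if isinstance(c, str):
        c = CONSTRAINTS[c]
    group_sets = {g: t.group_leaves(g) for g in c.groups}
    missing = [g for g, s in group_sets.items() if not s]
    if missing:
        raise ValueError(f"constraint {c.id} references group(s) absent from tree: {missing}")

    if c.id == P_NP_SPLIT:
        extra = t.leaves - group_sets[PERMISSIVE] - group_sets[NONPERMISSIVE]
        if extra:
            raise ValueError(f"{P_NP_SPLIT} applies to two-group trees; extra leaves: {sorted(extra)}")
        return split_compatible(t, group_sets[PERMISSIVE])

    t = _reroot(t, rooting, outgroup)
    if not all(clade_compatible(t, s) for s in group_sets.values()):
        return False
    if c.id == R_SISTER_NP:
        return clade_compatible(t, group_sets[RESISTANT] | group_sets[NONPERMISSIVE])
    return True


def screen_trees(
    trees: Sequence[LabeledGeneTree],
    m: GeneClusterMatrix | None = None,
    ph: PhenotypeMap | None = None,
    rooting: str = "as-parsed",
    outgroup: Iterable[str] | None = None,
) -> list[ScreenResult]:
    """Classify each gene tree by the most specific constraint it matches.

    Three-group trees are tested against ``R_SISTER_NP`` then ``ALL_MONO``
    (most specific first; a tree is reported under one constraint only).
    Two-group permissive/nonpermissive trees are tested against
    ``P_NP_SPLIT``. When a matrix is supplied, trees whose cluster is not
    single-copy across its leaf genomes are logged and skipped, and matched
    results carry the cluster's function annotations.
    """
    if not trees:
        warnings.warn("no trees to screen")
        return []
    results = []
    for t in trees:
        if m is not None and t.cluster_id in m._cluster_index:
            rows = m.genome_rows(t.leaves)
            col = m._cluster_index[t.cluster_id]
            if not (m.counts[rows, col] == 1).all():
                logger.warning(
                    "cluster %s is not single-copy across its %d leaf genomes; skipped",
                    t.cluster_id, len(t.leaves),
                )
                continue
        groups_present = set(t.leaf_to_group.values())
        matched = None
        if {RESISTANT, NONPERMISSIVE, PERMISSIVE} <= groups_present:
            for cid in (R_SISTER_NP, ALL_MONO):
                if matches_constraint(t, cid, rooting=rooting, outgroup=outgroup):
                    matched = cid
                    break
        elif groups_present == {PERMISSIVE, NONPERMISSIVE}:
            if matches_constraint(t, P_NP_SPLIT):
                matched = P_NP_SPLIT
        results.append(
            ScreenResult(
                cluster_id=t.cluster_id,
                matched=matched,
                n_internal_edges=t.n_internal_edges,
                functions=m.cluster_functions(t.cluster_id) if m is not None else set(),
            )
        )
    return results


def screen_summary(results: Sequence[ScreenResult]) -> dict[str, int]:
    """Per-constraint match counts, plus unmatched trees under ``none``."""
    summary = {cid: 0 for cid in CONSTRAINTS}
    summary["none"] = 0
    for r in results:
        summary[r.matched if r.matched else "none"] += 1
    return summary
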