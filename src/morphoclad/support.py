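"""Bremer (decay) support, strict consensus and unsupported-node collapse.

Bremer support of a group is the number of extra steps needed before a
tree lacking the group becomes optimal; it is computed here exactly, by an
anti-constrained branch-and-bound search over all binary topologies that
do not display the group's split.

Unsupported-node collapse contracts every internal branch whose minimum
optimised length is zero — i.e. branches on which no character is forced
to change under any most-parsimonious reconstruction (the "rule 1"
collapse convention).  A branch qualifies exactly when contracting it
leaves the tree length unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .datamodel import (
    CharacterMatrix,
    MorphocladError,
    Node,
    PhyloTree,
    canonical_label,
    tree_from_splits,
)
from .parsimony import (
    best_length_without_split,
    branch_and_bound_search,
    fitch_length,
)


@dataclass(frozen=True)
class SupportResult:
    """Bremer support of one clade.

    ``bremer`` = best length among trees lacking the clade minus the
    optimal length.  Values >= 1 mean the clade occurs in every optimal
    tree; values <= 0 mean some optimal tree already lacks it.
    """

    clade: frozenset[str]
    optimal_length: int
    best_length_without: int
    bremer: int


def bremer_support(matrix: CharacterMatrix, clade: Iterable[str]) -> SupportResult:
    """Exact Bremer support of ``clade`` (given as taxon names) on the
    matrix, interpreting the clade as an unrooted split."""
    members = frozenset(canonical_label(c) for c in clade)
    optimum = branch_and_bound_search(matrix).length
    without = best_length_without_split(matrix, members)
    return SupportResult(
        clade=members,
        optimal_length=optimum,
        best_length_without=without,
        bremer=without - optimum,
    )


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """The multifurcating tree displaying exactly the splits common to
    every input tree."""
    if not trees:
        raise MorphocladError("strict consensus of an empty tree set")
    leaf_sets = {frozenset(t.leaf_labels()) for t in trees}
    if len(leaf_sets) != 1:
        raise MorphocladError("trees have inconsistent leaf sets")
    shared = trees[0].splits()
    for t in trees[1:]:
        shared &= t.splits()
    return tree_from_splits(trees[0].leaf_labels(), shared)


def _contract_clusters(tree: PhyloTree,
                       doomed: set[frozenset[str]]) -> PhyloTree:
    """Copy of ``tree`` with every internal node whose leaf cluster is in
    ``doomed`` dissolved into its parent."""

    def rebuild(v: Node) -> tuple[Node, frozenset[str]]:
        if v.is_leaf:
            return Node(v.label), frozenset((v.label,))
        children: list[Node] = []
        below: frozenset[str] = frozenset()
        for c in v.children:
            new_c, c_below = rebuild(c)
            below |= c_below
            if not new_c.is_leaf and c_below in doomed:
                children.extend(new_c.children)
            else:
                children.append(new_c)
        return Node(None, children), below

    root, _ = rebuild(tree.root)
    return PhyloTree(root, rooted=tree.rooted)


def collapse_unsupported(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """Contract every internal branch of minimum optimised length zero.

    Iterates to a fixed point, so the operation is idempotent.  The
    result may be multifurcating; its length equals the input tree's
    length by construction.
    """
    current = tree
    total = fitch_length(current, matrix)
    while True:
        leaves = frozenset(current.leaf_labels())
        n = len(leaves)
        doomed: set[frozenset[str]] = set()
        for cluster in current.clusters():
            if len(cluster) < 2 or len(cluster) > n - 1:
                continue  # pendant edges and root cluster are never collapsed
            side = cluster if len(cluster) <= n - 2 else None
            if side is None:
                continue
            contracted = _contract_clusters(current, {cluster})
            if fitch_length(contracted, matrix) == total:
                doomed.add(cluster)
        if not doomed:
            return current
        current = _contract_clusters(current, doomed)
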