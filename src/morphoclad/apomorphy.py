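"""Outgroup rooting and apomorphy (character-state change) mapping.

Characters are optimised onto a rooted tree by unit-cost dynamic
programming (exact on polytomies), then resolved to a single assignment
under the ACCTRAN (accelerate: prefer a change on the higher branch when
tied) or DELTRAN (delay: prefer keeping the parental state) convention.
Each mapped change is classified relative to the root-inferred ancestral
state:

* ``unique_forward`` — the character changes exactly once on the tree,
  away from the ancestral state;
* ``homoplasious_forward`` — a change away from the ancestral state on a
  character that changes more than once;
* ``reversal`` — a change back to the ancestral state below an earlier
  forward change.

Changes whose branch placement differs between ACCTRAN and DELTRAN are
flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .datamodel import (
    MISSING,
    CharacterMatrix,
    MorphocladError,
    Node,
    PhyloTree,
    canonical_label,
)
from .parsimony import per_character_steps

UNIQUE_FORWARD = "unique_forward"
HOMOPLASIOUS_FORWARD = "homoplasious_forward"
REVERSAL = "reversal"

_BIG = 10 ** 9


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root an unrooted tree on the outgroup's pendant edge.

    The root becomes a bifurcation whose children are the outgroup leaf
    and the ingroup subtree; ingroup topology is unchanged.
    """
    target = canonical_label(outgroup)
    if target not in tree.leaf_labels():
        raise MorphocladError(f"outgroup {outgroup!r} is not a leaf of the tree")

    # adjacency over Node objects so we can re-hang the tree anywhere
    neighbors: dict[int, list[Node]] = {}
    nodes: dict[int, Node] = {}

    def link(a: Node, b: Node) -> None:
        neighbors.setdefault(id(a), []).append(b)
        neighbors.setdefault(id(b), []).append(a)
        nodes[id(a)] = a
        nodes[id(b)] = b

    stack = [tree.root]
    nodes[id(tree.root)] = tree.root
    neighbors.setdefault(id(tree.root), [])
    while stack:
        v = stack.pop()
        for c in v.children:
            link(v, c)
            stack.append(c)

    leaf = next(
        v for v in nodes.values() if v.is_leaf and v.label == target
    )
    anchor = neighbors[id(leaf)][0]

    def hang(v: Node, came_from: Node) -> Node:
        kids = [u for u in neighbors[id(v)] if u is not came_from]
        if not kids:
            return Node(v.label)
        return Node(v.label, [hang(u, v) for u in kids])

    root = Node(None, [Node(leaf.label), hang(anchor, leaf)])
    return PhyloTree(root, rooted=True)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Forget the root: return the same topology as an unrooted tree."""
    root = tree.root.copy()
    if len(root.children) == 2:
        a, b = root.children
        if not b.is_leaf:
            root = Node(None, [a] + b.children)
        elif not a.is_leaf:
            root = Node(None, a.children + [b])
    return PhyloTree(root, rooted=False)


@dataclass(frozen=True)
class Change:
    """One character-state change on one branch."""

    branch: frozenset[str]      # leaves subtended by the branch's child end
    character: int
    from_state: int
    to_state: int
    classification: str
    ambiguous: bool


@dataclass(frozen=True)
class ApomorphyMap:
    """All mapped changes plus the inferred root states."""

    changes: tuple[Change, ...]
    root_states: tuple[int, ...]
    resolution: str

    @property
    def total_changes(self) -> int:
        return len(self.changes)

    def by_character(self, index: int) -> tuple[Change, ...]:
        return tuple(c for c in self.changes if c.character == index)

    def by_branch(self, branch: frozenset[str]) -> tuple[Change, ...]:
        return tuple(c for c in self.changes if c.branch == branch)


def _resolve_states(
    tree: PhyloTree, matrix: CharacterMatrix, resolution: str,
    outgroup_label: Optional[str],
) -> tuple[list[tuple[frozenset[str], frozenset[str], int, int]], list[int]]:
    """Unit-cost DP over each character followed by a top-down pass.

    Returns (changes as (parent cluster, child cluster, char, to-state)
    -- from-state recoverable from parent assignment -- and root states).
    Tie at the root goes to the outgroup's observed state; ties on a
    branch go to "change" under acctran and "keep" under deltran.
    """
    rows = {t.label: matrix.states[i] for i, t in enumerate(matrix.taxa)}
    post = tree._postorder()
    children = {id(v): v.children for v in post}
    below: dict[int, frozenset[str]] = {}
    for v in post:
        if v.is_leaf:
            below[id(v)] = frozenset((v.label,))
        else:
            acc: frozenset[str] = frozenset()
            for c in v.children:
                acc |= below[id(c)]
            below[id(v)] = acc

    changes: list[tuple[frozenset[str], frozenset[str], int, int, int]] = []
    root_states: list[int] = []
    for j in range(matrix.nchar):
        cost: dict[int, tuple[int, int]] = {}
        for v in post:
            if v.is_leaf:
                s = int(rows[v.label][j])
                if s == MISSING:
                    cost[id(v)] = (0, 0)
                else:
                    cost[id(v)] = (0 if s == 0 else _BIG,
                                   0 if s == 1 else _BIG)
            else:
                c0 = c1 = 0
                for c in v.children:
                    k0, k1 = cost[id(c)]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k0 + 1, k1)
                cost[id(v)] = (c0, c1)

        r0, r1 = cost[id(tree.root)]
        if r0 < r1:
            root_state = 0
        elif r1 < r0:
            root_state = 1
        else:
            og = 0
            if outgroup_label is not None:
                s = int(rows[outgroup_label][j])
                og = s if s != MISSING else 0
            root_state = og
        root_states.append(root_state)

        stack = [(tree.root, root_state)]
        while stack:
            v, state = stack.pop()
            for c in v.children:
                k0, k1 = cost[id(c)]
                keep = (k0 if state == 0 else k1)
                flip = (k1 if state == 0 else k0) + 1
                if keep < flip:
                    child_state = state
                elif flip < keep:
                    child_state = 1 - state
                else:
                    child_state = (1 - state) if resolution == "acctran" else state
                if child_state != state:
                    changes.append(
                        (below[id(v)], below[id(c)], j, state, child_state)
                    )
                stack.append((c, child_state))
    out = [(p, b, j, s, t) for (p, b, j, s, t) in changes]
    return out, root_states


def map_apomorphies(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    resolution: str = "acctran",
) -> ApomorphyMap:
    """Optimise every character onto a rooted tree and classify changes.

    The tree must be rooted (see :func:`root_on_outgroup`); polytomies
    are scored with hard-polytomy semantics.  The per-character number of
    mapped changes always equals the character's Fitch step count.
    """
    if resolution not in ("acctran", "deltran"):
        raise MorphocladError(
            f"resolution must be 'acctran' or 'deltran', got {resolution!r}"
        )
    if not tree.rooted:
        raise MorphocladError("apomorphy mapping needs a rooted tree; "
                              "use root_on_outgroup first")
    og = matrix.outgroup
    og_label = og.label if og is not None else None

    expected = per_character_steps(tree, matrix)

    chosen, root_states = _resolve_states(tree, matrix, resolution, og_label)
    other, _ = _resolve_states(
        tree, matrix, "deltran" if resolution == "acctran" else "acctran",
        og_label,
    )
    other_keys = {(b, j) for (_p, b, j, _s, _t) in other}

    per_char: dict[int, int] = {}
    for (_p, _b, j, _s, _t) in chosen:
        per_char[j] = per_char.get(j, 0) + 1
    for j in range(matrix.nchar):
        if per_char.get(j, 0) != int(expected[j]):
            raise MorphocladError(
                f"internal inconsistency: character {j} mapped "
                f"{per_char.get(j, 0)} changes but Fitch length is "
                f"{int(expected[j])}"
            )

    result = []
    for (_parent, branch, j, s, t) in chosen:
        ancestral = root_states[j]
        n_changes = per_char[j]
        if t != ancestral:
            kind = UNIQUE_FORWARD if n_changes == 1 else HOMOPLASIOUS_FORWARD
        else:
            kind = REVERSAL
        result.append(
            Change(
                branch=branch,
                character=j,
                from_state=s,
                to_state=t,
                classification=kind,
                ambiguous=(branch, j) not in other_keys,
            )
        )
    return ApomorphyMap(
        changes=tuple(result),
        root_states=tuple(root_states),
        resolution=resolution,
    )


def apomorphy_table(amap: ApomorphyMap) -> str:
    """TSV rendering: branch (subtended leaves), character, states, class."""
    lines = ["branch\tcharacter\tfrom\tto\tclass\tambiguous"]
    for c in sorted(
        amap.changes, key=lambda c: (c.character, sorted(c.branch))
    ):
        branch = ",".join(sorted(c.branch))
        lines.append(
            f"{branch}\t{c.character}\t{c.from_state}\t{c.to_state}\t"
            f"{c.classification}\t{int(c.ambiguous)}"
        )
    return "\n".join(lines) + "\n"
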