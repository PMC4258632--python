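"""Core data types for morphology-based cladistic analysis.

The central objects are:

* :class:`CharacterMatrix` — a taxa x characters grid of binary states
  (with optional missing cells), the input to parsimony search.
* :class:`PhyloTree` — an unrooted (or outgroup-rooted) tree over the
  matrix taxa, multifurcation-capable.
* :class:`SpecimenRecord` — raw morphological observations on a single
  specimen (measurements in mm plus categorical traits), consumed by the
  character-coding and identification-key modules.
* :class:`BarcodeRecord` — a nucleotide barcode sequence kept alongside
  the morphological data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

MISSING = -1  # internal code for a missing / unscorable matrix cell

_VALID_ROLES = ("ingroup", "outgroup")


class MorphocladError(ValueError):
    """Base class for input/contract violations raised by this package."""


class MatrixFormatError(MorphocladError):
    """Malformed character-matrix input (parse errors, ragged grids...)."""


class TreeFormatError(MorphocladError):
    """Malformed tree input (unbalanced newick, unknown labels...)."""


def canonical_label(name: str) -> str:
    """Canonical taxon label: whitespace collapsed to underscores.

    Newick cannot carry bare spaces, so trees and matrices are matched on
    this canonical form while the original label is kept for display.
    """
    return "_".join(str(name).split())


@dataclass(frozen=True)
class Taxon:
    """A terminal taxon with its analysis role."""

    name: str
    role: str = "ingroup"

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise MorphocladError(
                f"taxon role must be one of {_VALID_ROLES}, got {self.role!r}"
            )

    @property
    def label(self) -> str:
        return canonical_label(self.name)


@dataclass(frozen=True)
class CharacterMeta:
    """Metadata for one character column (all characters unordered, weight 1)."""

    index: int
    description: str = ""
    ordering: str = "unordered"
    weight: int = 1


class CharacterMatrix:
    """Rectangular taxa x characters grid of states in {0, 1, missing}.

    Parameters
    ----------
    taxa
        Ordered taxa; names must be unique (after canonicalisation).
    states
        Sequence of rows, one per taxon, each a sequence of
        ``0``/``1``/``MISSING`` ints.
    characters
        Optional per-column metadata; defaults to bare indices.
    """

    def __init__(
        self,
        taxa: Sequence[Taxon | str],
        states: Sequence[Sequence[int]],
        characters: Optional[Sequence[CharacterMeta]] = None,
    ) -> None:
        self.taxa: list[Taxon] = [
            t if isinstance(t, Taxon) else Taxon(t) for t in taxa
        ]
        labels = [t.label for t in self.taxa]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise MatrixFormatError(f"duplicate taxon names: {dupes}")
        try:
            arr = np.asarray(states, dtype=np.int8)
        except ValueError as exc:
            raise MatrixFormatError(
                f"state grid must be rectangular: {exc}"
            ) from exc
        if arr.ndim != 2:
            raise MatrixFormatError("state grid must be rectangular (2-D)")
        if arr.shape[0] != len(self.taxa):
            raise MatrixFormatError(
                f"{len(self.taxa)} taxa but {arr.shape[0]} state rows"
            )
        bad = ~np.isin(arr, (0, 1, MISSING))
        if bad.any():
            raise MatrixFormatError(
                f"states must be 0, 1 or missing; offending values "
                f"{sorted(set(arr[bad].tolist()))}"
            )
        self.states: np.ndarray = arr
        if characters is None:
            characters = [CharacterMeta(j) for j in range(arr.shape[1])]
        self.characters: list[CharacterMeta] = list(characters)
        if len(self.characters) != arr.shape[1]:
            raise MatrixFormatError(
                f"{len(self.characters)} character records but "
                f"{arr.shape[1]} columns"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def ntax(self) -> int:
        return self.states.shape[0]

    @property
    def nchar(self) -> int:
        return self.states.shape[1]

    @property
    def taxon_labels(self) -> list[str]:
        return [t.label for t in self.taxa]

    @property
    def outgroup(self) -> Optional[Taxon]:
        out = [t for t in self.taxa if t.role == "outgroup"]
        return out[0] if out else None

    def row(self, name: str) -> np.ndarray:
        label = canonical_label(name)
        for i, t in enumerate(self.taxa):
            if t.label == label:
                return self.states[i]
        raise MorphocladError(f"unknown taxon {name!r}")

    def column(self, j: int) -> np.ndarray:
        return self.states[:, j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxon_labels == other.taxon_labels
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.ntax} taxa x {self.nchar} characters>"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A tree node; leaves carry a label, internal nodes carry children."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["Node"]] = None) -> None:
        self.label = label
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, [c.copy() for c in self.children])

    def __repr__(self) -> str:
        return f"Node({self.label!r})" if self.is_leaf else (
            f"Node<{len(self.children)} children>"
        )


class PhyloTree:
    """Tree over labelled leaves, stored rooted but unrooted by default.

    An unrooted tree is stored rooted at an arbitrary node; identity and
    comparisons go through the bipartition (split) set, so the storage
    rooting never matters.  Setting ``rooted=True`` marks a biologically
    rooted tree (e.g. after outgroup rooting); such trees additionally
    compare equal only when their rooted clusters agree.
    """

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted
        self._leaves: Optional[tuple[str, ...]] = None
        self._splits: Optional[frozenset[frozenset[str]]] = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_nested(cls, nested, rooted: bool = False) -> "PhyloTree":
        """Build from nested tuples/lists of labels, e.g. ``("A", ("B", "C"))``."""

        def build(x) -> Node:
            if isinstance(x, (tuple, list)):
                return Node(None, [build(c) for c in x])
            return Node(canonical_label(x))

        return cls(build(nested), rooted=rooted)

    # -- traversal -----------------------------------------------------------

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(v.children)

    def leaf_labels(self) -> tuple[str, ...]:
        if self._leaves is None:
            self._leaves = tuple(
                v.label for v in self._postorder() if v.is_leaf
            )
        return self._leaves

    def _postorder(self) -> list[Node]:
        order: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in reversed(v.children):
                    stack.append((c, False))
        return order

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    # -- splits --------------------------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each given as the side that does not
        contain the lexicographically smallest leaf label."""
        if self._splits is not None:
            return self._splits
        leaves = frozenset(self.leaf_labels())
        if len(leaves) != len(self.leaf_labels()):
            raise TreeFormatError("duplicate leaf labels in tree")
        ref = min(leaves)
        n = len(leaves)
        out: set[frozenset[str]] = set()

        def below(v: Node) -> frozenset[str]:
            if v.is_leaf:
                return frozenset((v.label,))
            got: frozenset[str] = frozenset()
            for c in v.children:
                got |= below(c)
            if 2 <= len(got) <= n - 2:
                side = got if ref not in got else leaves - got
                if len(side) >= 2:
                    out.add(side)
            return got

        below(self.root)
        self._splits = frozenset(out)
        return self._splits

    def clusters(self) -> frozenset[frozenset[str]]:
        """Rooted clusters (leaf sets below each internal node except root)."""
        out: set[frozenset[str]] = set()

        def below(v: Node) -> frozenset[str]:
            if v.is_leaf:
                return frozenset((v.label,))
            got: frozenset[str] = frozenset()
            for c in v.children:
                got |= below(c)
            out.add(got)
            return got

        root_cluster = below(self.root)
        out.discard(root_cluster)
        return frozenset(out)

    def is_binary_unrooted(self) -> bool:
        """True when every internal vertex has unrooted degree exactly 3."""
        for v in self.iter_nodes():
            if v.is_leaf:
                continue
            degree = len(v.children) + (0 if v is self.root else 1)
            if v is self.root:
                # storage root of an unrooted tree: needs 3 neighbours,
                # or 2 when it is a rooted tree's true root
                ok = degree == 3 or (self.rooted and degree == 2)
            else:
                ok = degree == 3
            if not ok:
                return False
        return True

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), rooted=self.rooted)

    # -- identity ------------------------------------------------------------

    def _key(self):
        if self.rooted:
            return (True, frozenset(self.leaf_labels()), self.clusters())
        return (False, frozenset(self.leaf_labels()), self.splits())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"


def tree_from_splits(
    leaf_labels: Iterable[str],
    splits: Iterable[frozenset[str]],
) -> PhyloTree:
    """Reconstruct the (possibly multifurcating) unrooted tree displaying
    exactly the given pairwise-compatible splits.

    Each split must be oriented as the side not containing the reference
    leaf (the lexicographically smallest label), matching
    :meth:`PhyloTree.splits`.
    """
    leaves = sorted(set(canonical_label(x) for x in leaf_labels))
    ref = leaves[0]
    clusters = sorted(
        {frozenset(s) for s in splits}, key=len, reverse=True
    )
    for c in clusters:
        if ref in c or not c or not c.issubset(leaves):
            raise TreeFormatError(f"split {sorted(c)} not oriented away from "
                                  f"reference leaf {ref!r} or has unknown labels")
    cluster_nodes = {c: Node() for c in clusters}
    root = Node()
    all_set = frozenset(leaves)
    parents: dict[frozenset[str], Node] = {all_set: root}

    def smallest_container(target: frozenset[str]) -> Node:
        best = None
        for c in clusters:
            if target < c and (best is None or len(c) < len(best)):
                best = c
        return cluster_nodes[best] if best is not None else root

    for c in clusters:
        smallest_container(c).children.append(cluster_nodes[c])
    for leaf in leaves:
        smallest_container(frozenset((leaf,))).children.append(Node(leaf))
    return PhyloTree(root, rooted=False)


@dataclass(frozen=True)
class BarcodeRecord:
    """A nucleotide barcode sequence with its accession identifier."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTRYSWKMBDHVN-")
        if bad:
            raise MorphocladError(f"invalid nucleotide symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpecimenRecord:
    """Raw observations on one specimen.

    measurements
        Named lengths/widths in millimetres, strictly positive.
    categorical
        Named trait levels: shape classes (e.g. dorsal-seta shapes),
        booleans (e.g. whether tergite VIII covers the cauda) and
        non-negative integer counts (e.g. pseudosensoria per hind tibia,
        antennal segment number).
    """

    measurements: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.measurements.items():
            if not (float(value) > 0.0):
                raise MorphocladError(
                    f"measurement {name!r} must be strictly positive, "
                    f"got {value!r}"
                )
        for name, value in self.categorical.items():
            if isinstance(value, int) and not isinstance(value, bool):
                if value < 0:
                    raise MorphocladError(
                        f"count {name!r} must be non-negative, got {value}"
                    )
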