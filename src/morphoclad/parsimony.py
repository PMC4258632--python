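"""Fitch parsimony scoring and optimal-tree search.

Binary characters are packed two bits per character into machine integers,
so a Fitch down-pass over all characters is a handful of bitwise operations
per internal node.  Three search strategies are provided:

* :func:`exhaustive_search` — scores every unrooted binary topology by
  stepwise leaf addition onto every edge (all (2n-5)!! of them);
* :func:`branch_and_bound_search` — same enumeration, pruning any partial
  tree already longer than the incumbent (tree length is monotone under
  leaf addition, so pruning is exact);
* :func:`ratchet_search` — the parsimony-ratchet heuristic: alternating
  NNI hill-climbs on a reweighted and the original matrix.

Scoring of arbitrary (possibly multifurcating) trees goes through
:func:`fitch_length`, which uses Hartigan-style state counting and is
therefore exact on hard polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .datamodel import (
    MISSING,
    CharacterMatrix,
    MorphocladError,
    PhyloTree,
    canonical_label,
    tree_from_splits,
)

_INF = float("inf")


# ---------------------------------------------------------------------------
# Bit packing
# ---------------------------------------------------------------------------


def _pack_codes(matrix: CharacterMatrix,
                weights: Optional[Sequence[int]] = None) -> tuple[list[int], int]:
    """Pack each taxon's states into one int, two bits per character copy.

    Integer character weights are realised by duplicating the character's
    bit slot.  Returns (leaf codes in taxon order, mask with the low bit of
    every slot set).
    """
    if weights is None:
        weights = [1] * matrix.nchar
    slots: list[tuple[int, int]] = []  # (char index, slot position)
    pos = 0
    for j, w in enumerate(weights):
        if w < 0:
            raise MorphocladError(f"negative character weight at {j}")
        for _ in range(int(w)):
            slots.append((j, pos))
            pos += 1
    mask01 = 0
    for _, p in slots:
        mask01 |= 1 << (2 * p)
    codes = []
    for row in matrix.states:
        code = 0
        for j, p in slots:
            s = int(row[j])
            if s == MISSING:
                code |= 3 << (2 * p)
            else:
                code |= 1 << (2 * p + s)
        codes.append(code)
    codes.extend([0] * (matrix.ntax - 2))  # zero slots for internal nodes
    return codes, mask01


class _Cut(Exception):
    """Internal: score exceeded the cutoff."""


def _score_adjacency(adj: list[list[int]], codes: list[int],
                     mask01: int, cutoff: float) -> Optional[int]:
    """Fitch length of the binary tree in `adj`, rooted at leaf 0.

    Returns None as soon as the running step count exceeds `cutoff`.
    """
    steps = 0

    def down(v: int, parent: int) -> int:
        nonlocal steps
        c = codes[v]
        if c:
            return c
        acc = 0
        for u in adj[v]:
            if u == parent:
                continue
            b = down(u, v)
            if acc == 0:
                acc = b
            else:
                x = acc & b
                conflict = mask01 & ~(x | (x >> 1))
                if conflict:
                    steps += conflict.bit_count()
                    if steps > cutoff:
                        raise _Cut
                    acc = x | ((acc | b) & (conflict * 3))
                else:
                    acc = x
        return acc

    try:
        top = down(adj[0][0], 0)
        x = top & codes[0]
        conflict = mask01 & ~(x | (x >> 1))
        steps += conflict.bit_count()
        if steps > cutoff:
            return None
    except _Cut:
        return None
    return steps


def _split_masks(adj: list[list[int]], n: int) -> frozenset[int]:
    """Non-trivial split bitmasks of the tree in `adj`, each oriented as
    the side not containing leaf 0."""
    masks: set[int] = set()

    def down(v: int, parent: int) -> int:
        if v < n:
            return 1 << v
        m = 0
        for u in adj[v]:
            if u != parent:
                m |= down(u, v)
        k = m.bit_count()
        if 2 <= k <= n - 2:
            masks.add(m)
        return m

    down(adj[0][0], 0)
    return frozenset(masks)


def _tree_from_masks(masks: Iterable[int], labels: Sequence[str]) -> PhyloTree:
    names = [canonical_label(x) for x in labels]
    ref = min(names)
    full = frozenset(names)
    splits = []
    for m in masks:
        side = frozenset(names[i] for i in range(len(names)) if m >> i & 1)
        if ref in side:
            side = full - side
        splits.append(side)
    return tree_from_splits(names, splits)


# ---------------------------------------------------------------------------
# Generic tree scoring (polytomy-exact, Hartigan counting)
# ---------------------------------------------------------------------------


def per_character_steps(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Minimum state changes per character on the given tree.

    Works on binary and multifurcating trees alike (hard-polytomy
    semantics: a polytomy is scored as given, never implicitly resolved).
    The result is independent of where the tree happens to be rooted.
    """
    tree_leaves = set(tree.leaf_labels())
    matrix_taxa = set(matrix.taxon_labels)
    if tree_leaves != matrix_taxa:
        only_tree = sorted(tree_leaves - matrix_taxa)
        only_matrix = sorted(matrix_taxa - tree_leaves)
        raise MorphocladError(
            "tree leaves and matrix taxa differ: "
            f"only in tree {only_tree}, only in matrix {only_matrix}"
        )
    rows = {t.label: matrix.states[i] for i, t in enumerate(matrix.taxa)}
    nchar = matrix.nchar
    steps = np.zeros(nchar, dtype=np.int64)
    memo: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v in tree._postorder():
        if v.is_leaf:
            row = rows[v.label]
            in0 = (row == 0) | (row == MISSING)
            in1 = (row == 1) | (row == MISSING)
        else:
            c0 = np.zeros(nchar, dtype=np.int64)
            c1 = np.zeros(nchar, dtype=np.int64)
            for child in v.children:
                a0, a1 = memo.pop(id(child))
                c0 += a0
                c1 += a1
            best = np.maximum(c0, c1)
            steps += len(v.children) - best
            in0 = c0 == best
            in1 = c1 == best
        memo[id(v)] = (in0, in1)
    return steps


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Total parsimony length (sum of per-character minimum changes)."""
    return int(per_character_steps(tree, matrix).sum())


# ---------------------------------------------------------------------------
# Enumeration of unrooted binary topologies
# ---------------------------------------------------------------------------


def n_unrooted_topologies(n_leaves: int) -> int:
    """(2n-5)!! — the number of distinct unrooted binary topologies."""
    count = 1
    for k in range(4, n_leaves + 1):
        count *= 2 * k - 5
    return count


def enumerate_trees(leaf_labels: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on the given leaves once,
    generated by stepwise addition of each leaf onto every edge."""
    labels = [canonical_label(x) for x in leaf_labels]
    n = len(labels)
    if n < 3:
        raise MorphocladError("need at least 3 leaves to enumerate topologies")
    if len(set(labels)) != n:
        raise MorphocladError("leaf labels must be unique")
    for adj in _enumerate_adjacency(n):
        yield _tree_from_masks(_split_masks(adj, n), labels)


def _init_adjacency(n: int) -> tuple[list[list[int]], list[tuple[int, int]]]:
    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
    hub = n
    for leaf in range(3):
        adj[leaf].append(hub)
        adj[hub].append(leaf)
    edges = [(0, hub), (1, hub), (2, hub)]
    return adj, edges


def _enumerate_adjacency(n: int) -> Iterator[list[list[int]]]:
    adj, edges = _init_adjacency(n)
    if n == 3:
        yield adj
        return

    def recurse(k: int) -> Iterator[list[list[int]]]:
        w = n + k - 2
        for i in range(len(edges)):
            u, v = edges[i]
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, k]
            adj[k].append(w)
            edges[i] = (u, w)
            edges.append((w, v))
            edges.append((w, k))
            if k + 1 == n:
                yield adj
            else:
                yield from recurse(k + 1)
            edges.pop()
            edges.pop()
            edges[i] = (u, v)
            adj[k].pop()
            adj[w] = []
            adj[u].remove(w)
            adj[u].append(v)
            adj[v].remove(w)
            adj[v].append(u)

    yield from recurse(3)


# ---------------------------------------------------------------------------
# Search results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an optimal-tree search.

    ``trees`` holds every optimal topology (deduplicated by split set);
    ``near_optimal`` additionally holds every topology within ``slack``
    steps of the optimum, as (tree, length) pairs, when slack > 0.
    """

    length: int
    trees: tuple[PhyloTree, ...]
    trees_examined: int
    method: str
    slack: int = 0
    near_optimal: tuple[tuple[PhyloTree, int], ...] = ()

    def __post_init__(self) -> None:
        if any(l < self.length for _, l in self.near_optimal):
            raise MorphocladError("near-optimal tree shorter than optimum")


@dataclass(frozen=True)
class RatchetConfig:
    """Parsimony-ratchet settings (defaults follow the published run:
    5000 iterations per rep, 5 trees held, 1 character resampled)."""

    iterations: int = 5000
    trees_held: int = 5
    characters_reweighted: int = 1
    reweight_factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("iterations", "trees_held", "characters_reweighted"):
            if getattr(self, name) < 1:
                raise MorphocladError(f"{name} must be >= 1")
        if self.reweight_factor < 2:
            raise MorphocladError("reweight_factor must be >= 2")


# ---------------------------------------------------------------------------
# Exact searches
# ---------------------------------------------------------------------------


def _run_search(
    matrix: CharacterMatrix,
    *,
    prune_partial: bool,
    slack: int = 0,
    forbidden_mask: Optional[int] = None,
    initial_bound: float = _INF,
) -> tuple[float, dict[frozenset[int], int], int]:
    """Shared stepwise-addition search core.

    Returns (best length, {split-mask set -> length} for every kept full
    tree, number of complete topologies scored).  With `forbidden_mask`
    set, only trees lacking that split are eligible as results (used for
    Bremer decay searches); enumeration still spans all topologies.
    """
    n = matrix.ntax
    codes, mask01 = _pack_codes(matrix)
    best = initial_bound
    found: dict[frozenset[int], int] = {}
    examined = 0

    if n == 3:
        adj, _ = _init_adjacency(n)
        length = _score_adjacency(adj, codes, mask01, _INF)
        key = _split_masks(adj, n)
        if forbidden_mask is None or forbidden_mask not in key:
            return float(length), {key: int(length)}, 1
        return _INF, {}, 1

    adj, edges = _init_adjacency(n)

    def handle_full() -> None:
        nonlocal best, examined
        examined += 1
        length = _score_adjacency(adj, codes, mask01, best + slack)
        if length is None:
            return
        masks = _split_masks(adj, n)
        if forbidden_mask is not None and forbidden_mask in masks:
            return
        if length < best:
            best = length
            limit = best + slack
            for key in [k for k, l in found.items() if l > limit]:
                del found[key]
        if length <= best + slack:
            found[masks] = length

    def recurse(k: int) -> None:
        w = n + k - 2
        for i in range(len(edges)):
            u, v = edges[i]
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, k]
            adj[k].append(w)
            edges[i] = (u, w)
            edges.append((w, v))
            edges.append((w, k))
            descend = True
            if prune_partial and best + slack < _INF:
                descend = (
                    _score_adjacency(adj, codes, mask01, best + slack)
                    is not None
                )
            if descend:
                if k + 1 == n:
                    handle_full()
                else:
                    recurse(k + 1)
            edges.pop()
            edges.pop()
            edges[i] = (u, v)
            adj[k].pop()
            adj[w] = []
            adj[u].remove(w)
            adj[u].append(v)
            adj[v].remove(w)
            adj[v].append(u)

    recurse(3)
    return best, found, examined


def _greedy_addition_length(matrix: CharacterMatrix,
                            order: Optional[Sequence[int]] = None) -> int:
    """Length of a greedy stepwise-addition tree — an upper bound used to
    seed branch-and-bound."""
    adj, length = _greedy_addition_tree(matrix, order)
    return length


def _greedy_addition_tree(
    matrix: CharacterMatrix, order: Optional[Sequence[int]] = None
) -> tuple[list[list[int]], int]:
    n = matrix.ntax
    codes, mask01 = _pack_codes(matrix)
    return _greedy_addition_adj(codes, mask01, n, order)


def _greedy_addition_adj(
    codes: list[int], mask01: int, n: int,
    order: Optional[Sequence[int]] = None,
) -> tuple[list[list[int]], int]:
    if order is None:
        order = list(range(n))
    relabel = {new: old for new, old in enumerate(order)}
    local_codes = [codes[relabel[i]] for i in range(n)] + [0] * (n - 2)
    adj, edges = _init_adjacency(n)
    if n > 3:
        for k in range(3, n):
            w = n + k - 2
            best_i, best_len = 0, _INF
            for i in range(len(edges)):
                u, v = edges[i]
                adj[u].remove(v)
                adj[v].remove(u)
                adj[u].append(w)
                adj[v].append(w)
                adj[w] = [u, v, k]
                adj[k].append(w)
                length = _score_adjacency(adj, local_codes, mask01, _INF)
                if length < best_len:
                    best_i, best_len = i, length
                adj[k].pop()
                adj[w] = []
                adj[u].remove(w)
                adj[u].append(v)
                adj[v].remove(w)
                adj[v].append(u)
            u, v = edges[best_i]
            adj[u].remove(v)
            adj[v].remove(u)
            adj[u].append(w)
            adj[v].append(w)
            adj[w] = [u, v, k]
            adj[k].append(w)
            edges[best_i] = (u, w)
            edges.append((w, v))
            edges.append((w, k))
    # map local leaf ids back to original taxon ids
    size = 2 * n - 2
    remap = list(range(size))
    for new in range(n):
        remap[new] = relabel[new]
    out: list[list[int]] = [[] for _ in range(size)]
    for v in range(size):
        for u in adj[v]:
            out[remap[v]].append(remap[u])
    length = _score_adjacency(out, codes, mask01, _INF)
    return out, int(length)


def _result_from_found(
    found: dict[frozenset[int], int], best: float, labels: Sequence[str],
    examined: int, method: str, slack: int,
) -> SearchResult:
    if best == _INF:
        raise MorphocladError("search found no admissible tree")
    items = sorted(found.items(), key=lambda kv: (kv[1], sorted(kv[0])))
    optimal = tuple(
        _tree_from_masks(k, labels) for k, l in items if l == best
    )
    near = tuple(
        (_tree_from_masks(k, labels), l) for k, l in items
    ) if slack > 0 else ()
    return SearchResult(
        length=int(best),
        trees=optimal,
        trees_examined=examined,
        method=method,
        slack=slack,
        near_optimal=near,
    )


def exhaustive_search(
    matrix: CharacterMatrix, slack: int = 0, max_taxa: int = 12
) -> SearchResult:
    """Score every unrooted binary topology and return the optima.

    With ``slack`` s > 0, every topology within s steps of the optimum is
    additionally reported.  Guarded at ``max_taxa`` because the topology
    count grows as (2n-5)!!; use :func:`branch_and_bound_search` or
    :func:`ratchet_search` beyond that.
    """
    _check_searchable(matrix)
    if matrix.ntax > max_taxa:
        raise MorphocladError(
            f"{matrix.ntax} taxa exceeds the exhaustive guard of {max_taxa}; "
            "use branch_and_bound_search or ratchet_search"
        )
    best, found, examined = _run_search(
        matrix, prune_partial=False, slack=slack
    )
    return _result_from_found(
        found, best, matrix.taxon_labels, examined, "exhaustive", slack
    )


def branch_and_bound_search(
    matrix: CharacterMatrix, slack: int = 0
) -> SearchResult:
    """Exact search pruning partial trees longer than the incumbent.

    Returns the same optimal set and length as :func:`exhaustive_search`;
    a greedy stepwise-addition tree seeds the initial upper bound.
    """
    _check_searchable(matrix)
    bound = _greedy_addition_length(matrix)
    best, found, examined = _run_search(
        matrix, prune_partial=True, slack=slack, initial_bound=float(bound)
    )
    return _result_from_found(
        found, best, matrix.taxon_labels, examined, "branch_and_bound", slack
    )


def _check_searchable(matrix: CharacterMatrix) -> None:
    if matrix.ntax < 3:
        raise MorphocladError("need at least 3 taxa to search tree space")


def clade_mask(matrix: CharacterMatrix, clade: Iterable[str]) -> int:
    """Bitmask (in matrix taxon order) of a clade, oriented as the side
    not containing the first taxon; validates the names."""
    labels = matrix.taxon_labels
    index = {name: i for i, name in enumerate(labels)}
    members = [canonical_label(c) for c in clade]
    unknown = sorted(set(members) - set(labels))
    if unknown:
        raise MorphocladError(f"clade names not in matrix: {unknown}")
    mask = 0
    for m in members:
        mask |= 1 << index[m]
    size = mask.bit_count()
    if size < 2 or size > matrix.ntax - 2:
        raise MorphocladError(
            "clade must be a non-trivial split "
            f"(2..{matrix.ntax - 2} taxa), got {size}"
        )
    if mask & 1:  # orient away from taxon 0, matching search-internal masks
        mask = ((1 << matrix.ntax) - 1) ^ mask
    return mask


def best_length_without_split(matrix: CharacterMatrix,
                              clade: Iterable[str]) -> int:
    """Exact minimum length over all binary topologies NOT displaying the
    given split (the anti-constrained search behind Bremer support)."""
    _check_searchable(matrix)
    mask = clade_mask(matrix, clade)
    best, _found, _examined = _run_search(
        matrix, prune_partial=True, forbidden_mask=mask
    )
    if best == _INF:
        raise MorphocladError("no topology lacks the requested split")
    return int(best)


# ---------------------------------------------------------------------------
# Parsimony ratchet
# ---------------------------------------------------------------------------


def _nni_neighbors(adj: list[list[int]], n: int) -> Iterator[list[list[int]]]:
    """The two nearest-neighbour interchanges around every internal edge."""
    seen = set()
    for u in range(n, 2 * n - 2):
        for v in adj[u]:
            if v < n or (v, u) in seen:
                continue
            seen.add((u, v))
            a = next(x for x in adj[u] if x != v)
            others = [x for x in adj[v] if x != u]
            for c in others:
                new = [list(row) for row in adj]
                new[u].remove(a)
                new[u].append(c)
                new[a].remove(u)
                new[a].append(v)
                new[v].remove(c)
                new[v].append(a)
                new[c].remove(v)
                new[c].append(u)
                yield new


def _hill_climb(adj: list[list[int]], codes: list[int], mask01: int,
                n: int, counter: list[int]) -> tuple[list[list[int]], int]:
    current = [list(row) for row in adj]
    length = _score_adjacency(current, codes, mask01, _INF)
    counter[0] += 1
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current, n):
            cand_len = _score_adjacency(cand, codes, mask01, length)
            counter[0] += 1
            if cand_len is not None and cand_len < length:
                current, length = cand, cand_len
                improved = True
                break
    return current, int(length)


def ratchet_search(matrix: CharacterMatrix,
                   config: RatchetConfig = RatchetConfig()) -> SearchResult:
    """Parsimony-ratchet heuristic search.

    Each iteration upweights a small random character sample (x
    ``reweight_factor``), hill-climbs under the perturbed weights, then
    hill-climbs the result under the original weights; up to
    ``trees_held`` distinct best trees are retained between iterations.
    Fully reproducible under ``config.seed``; the reported length is an
    upper bound on (and in practice equal to) the true optimum.
    """
    _check_searchable(matrix)
    n = matrix.ntax
    rng = np.random.default_rng(config.seed)
    codes, mask01 = _pack_codes(matrix)
    scored = [0]

    order = list(rng.permutation(n))
    start, start_len = _greedy_addition_adj(codes, mask01, n, order)
    current, best_len = _hill_climb(start, codes, mask01, n, scored)
    pool: dict[frozenset[int], tuple[list[list[int]], int]] = {
        _split_masks(current, n): (current, best_len)
    }
    best_trees = dict(pool)

    for _ in range(config.iterations):
        sampled = rng.choice(
            matrix.nchar, size=min(config.characters_reweighted, matrix.nchar),
            replace=False,
        )
        weights = [1] * matrix.nchar
        for j in sampled:
            weights[int(j)] = config.reweight_factor
        wcodes, wmask01 = _pack_codes(matrix, weights)

        keys = sorted(pool, key=sorted)
        seed_key = keys[int(rng.integers(len(keys)))]
        seed_adj = pool[seed_key][0]

        perturbed, _ = _hill_climb(seed_adj, wcodes, wmask01, n, scored)
        candidate, cand_len = _hill_climb(perturbed, codes, mask01, n, scored)

        key = _split_masks(candidate, n)
        pool[key] = (candidate, cand_len)
        if len(pool) > config.trees_held:
            worst = max(
                pool, key=lambda k: (pool[k][1], sorted(k))
            )
            del pool[worst]
        if cand_len < best_len:
            best_len = cand_len
            best_trees = {key: (candidate, cand_len)}
        elif cand_len == best_len:
            best_trees[key] = (candidate, cand_len)

    labels = matrix.taxon_labels
    trees = tuple(
        _tree_from_masks(k, labels)
        for k in sorted(best_trees, key=sorted)
    )
    return SearchResult(
        length=int(best_len),
        trees=trees,
        trees_examined=scored[0],
        method="ratchet",
    )
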