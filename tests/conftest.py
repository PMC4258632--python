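"""Shared fixtures: the bundled study data, its optimal trees, and an
exponential brute-force parsimony oracle independent of the package's
Fitch/Hartigan machinery."""

from __future__ import annotations

import itertools

import pytest

from morphoclad import (
    branch_and_bound_search,
    load_siphini_matrix,
    parse_newick,
)
from morphoclad.fixtures import REFERENCE_TOPOLOGY_NEWICK

ATHEROIDES_PAIR = frozenset(
    ["Atheroides_vallescaldera", "Atheroides_serrulatus"]
)


@pytest.fixture(scope="session")
def siphini_matrix():
    return load_siphini_matrix()


@pytest.fixture(scope="session")
def siphini_optima(siphini_matrix):
    """All optimal binary topologies of the bundled matrix (exact search)."""
    return branch_and_bound_search(siphini_matrix)


@pytest.fixture(scope="session")
def reference_tree():
    return parse_newick(REFERENCE_TOPOLOGY_NEWICK)


def brute_force_min_changes(tree, column_by_leaf) -> int:
    """Minimum changes of one binary character on a tree, by enumerating
    every assignment of states to internal nodes (exponential; oracle
    for small trees only)."""
    post = tree._postorder()
    internal = [v for v in post if not v.is_leaf]
    edges = [(v, c) for v in post for c in v.children]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = {id(v): s for v, s in zip(internal, assignment)}
        for v in post:
            if v.is_leaf:
                state[id(v)] = column_by_leaf[v.label]
        cost = sum(state[id(a)] != state[id(b)] for a, b in edges)
        if best is None or cost < best:
            best = cost
    return best


@pytest.fixture(scope="session")
def brute_force_oracle():
    return brute_force_min_changes
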