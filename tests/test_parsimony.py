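"""Fitch scoring, topology enumeration and the three search strategies."""

import numpy as np
import pytest

from morphoclad import (
    CharacterMatrix,
    MorphocladError,
    RatchetConfig,
    SimulationConfig,
    Taxon,
    branch_and_bound_search,
    enumerate_trees,
    exhaustive_search,
    fitch_length,
    n_unrooted_topologies,
    parse_newick,
    per_character_steps,
    ratchet_search,
    simulate_characters,
)
from morphoclad.metrics import max_steps, min_steps
from morphoclad.simulate import random_topology

from conftest import ATHEROIDES_PAIR


def toy_matrix(rows, names=None):
    names = names or [chr(ord("A") + i) for i in range(len(rows))]
    return CharacterMatrix([Taxon(n) for n in names], rows)


class TestEnumeration:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_counts_match_double_factorial(self, n):
        labels = [f"t{i}" for i in range(n)]
        trees = list(enumerate_trees(labels))
        assert len(trees) == n_unrooted_topologies(n)
        # all distinct
        assert len(set(trees)) == len(trees)

    def test_ten_leaf_count_formula(self):
        assert n_unrooted_topologies(10) == 2_027_025

    def test_too_few_leaves(self):
        with pytest.raises(MorphocladError):
            next(enumerate_trees(["A", "B"]))


class TestFitchScoring:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed, brute_force_oracle):
        """Per-character Fitch steps equal exponential brute-force
        minimisation over all internal-state assignments."""
        tree = random_topology([f"t{i}" for i in range(6)], seed)
        matrix = simulate_characters(
            tree, SimulationConfig(6, 0.3, seed + 100)
        )
        steps = per_character_steps(tree, matrix)
        for j in range(matrix.nchar):
            column = {t: int(matrix.row(t)[j]) for t in matrix.taxon_labels}
            assert brute_force_oracle(tree, column) == steps[j]

    def test_single_minority_taxon_costs_one(self):
        matrix = toy_matrix([[0], [1], [1], [1], [1]])
        for tree in enumerate_trees(matrix.taxon_labels):
            assert fitch_length(tree, matrix) == 1

    def test_root_choice_irrelevant(self, siphini_matrix, siphini_optima):
        tree = siphini_optima.trees[0]
        # same unrooted topology written with different nestings
        from morphoclad import write_newick
        from morphoclad.apomorphy import root_on_outgroup, unroot

        rerooted = unroot(
            root_on_outgroup(tree, "Sipha_flava")
        )
        assert rerooted == tree
        assert fitch_length(rerooted, siphini_matrix) == fitch_length(
            tree, siphini_matrix
        )

    def test_taxon_order_irrelevant(self, siphini_matrix, siphini_optima):
        order = np.random.default_rng(5).permutation(siphini_matrix.ntax)
        shuffled = CharacterMatrix(
            [siphini_matrix.taxa[i] for i in order],
            siphini_matrix.states[order],
        )
        assert fitch_length(
            siphini_optima.trees[0], shuffled
        ) == siphini_optima.length

    def test_leaf_mismatch_lists_difference(self, siphini_matrix):
        tree = parse_newick("(A,B,(C,D));")
        with pytest.raises(MorphocladError, match="only in tree"):
            fitch_length(tree, siphini_matrix)

    def test_star_tree_scores_worst_case(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 2, size=(6, 8))
        matrix = toy_matrix(rows.tolist())
        star = parse_newick("(" + ",".join(matrix.taxon_labels) + ");")
        expected = sum(max_steps(matrix.column(j)) for j in range(8))
        assert fitch_length(star, matrix) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_steps_within_conceivable_bounds(self, seed):
        tree = random_topology([f"t{i}" for i in range(7)], seed)
        matrix = simulate_characters(tree, SimulationConfig(15, 0.25, seed))
        steps = per_character_steps(tree, matrix)
        for j in range(matrix.nchar):
            assert min_steps(matrix.column(j)) <= steps[j]
            assert steps[j] <= max_steps(matrix.column(j))


class TestExactSearches:
    def test_perfectly_compatible_four_taxa(self):
        matrix = toy_matrix([[1, 0], [1, 0], [0, 1], [0, 1]])
        result = exhaustive_search(matrix)
        assert result.length == 2
        assert len(result.trees) == 1
        assert result.trees[0].splits() == frozenset(
            {frozenset({"C", "D"})}
        )
        assert result.trees_examined == 3

    def test_constant_matrix_any_tree_optimal(self):
        matrix = toy_matrix([[0, 0]] * 5)
        result = exhaustive_search(matrix)
        assert result.length == 0
        assert len(result.trees) == n_unrooted_topologies(5)

    def test_taxon_guard_refuses_blowup(self):
        matrix = toy_matrix([[0]] * 13)
        with pytest.raises(MorphocladError, match="branch_and_bound"):
            exhaustive_search(matrix)

    @pytest.mark.parametrize("seed", range(10))
    def test_branch_and_bound_equals_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        matrix = toy_matrix(rng.integers(0, 2, size=(7, 9)).tolist())
        ex = exhaustive_search(matrix)
        bb = branch_and_bound_search(matrix)
        assert bb.length == ex.length
        assert set(bb.trees) == set(ex.trees)

    def test_slack_collects_all_near_optimal(self):
        rng = np.random.default_rng(42)
        matrix = toy_matrix(rng.integers(0, 2, size=(6, 8)).tolist())
        result = branch_and_bound_search(matrix, slack=2)
        # oracle: score every topology directly
        by_tree = {
            t: fitch_length(t, matrix)
            for t in enumerate_trees(matrix.taxon_labels)
        }
        expected = {
            t: l for t, l in by_tree.items()
            if l <= min(by_tree.values()) + 2
        }
        assert dict(result.near_optimal) == expected

    def test_fixture_optimum(self, siphini_matrix, siphini_optima):
        assert siphini_optima.length == 14
        full = frozenset(siphini_matrix.taxon_labels)
        for tree in siphini_optima.trees:
            sides = tree.splits() | {full - s for s in tree.splits()}
            assert ATHEROIDES_PAIR in sides


class TestRatchet:
    def test_finds_fixture_optimum_and_is_deterministic(self, siphini_matrix):
        config = RatchetConfig(iterations=200, seed=1)
        first = ratchet_search(siphini_matrix, config)
        second = ratchet_search(siphini_matrix, config)
        assert first.length == 14
        assert first.length == second.length
        assert first.trees == second.trees

    @pytest.mark.parametrize("seed", range(3))
    def test_never_beats_exact_optimum(self, seed):
        rng = np.random.default_rng(seed + 50)
        matrix = toy_matrix(rng.integers(0, 2, size=(7, 10)).tolist())
        exact = branch_and_bound_search(matrix).length
        heur = ratchet_search(
            matrix, RatchetConfig(iterations=30, seed=seed)
        ).length
        assert heur >= exact

    def test_config_validation(self):
        with pytest.raises(MorphocladError):
            RatchetConfig(iterations=0)
        with pytest.raises(MorphocladError):
            RatchetConfig(trees_held=0)
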