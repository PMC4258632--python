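"""Outgroup rooting and apomorphy mapping / change classification."""

import numpy as np
import pytest

from morphoclad import (
    CharacterMatrix,
    MorphocladError,
    SimulationConfig,
    Taxon,
    map_apomorphies,
    per_character_steps,
    root_on_outgroup,
    simulate_characters,
)
from morphoclad.apomorphy import (
    HOMOPLASIOUS_FORWARD,
    REVERSAL,
    UNIQUE_FORWARD,
    unroot,
)
from morphoclad.fixtures import OUTGROUP
from morphoclad.simulate import random_topology

from conftest import ATHEROIDES_PAIR


@pytest.fixture(scope="module")
def rooted_reference(reference_tree):
    return root_on_outgroup(reference_tree, OUTGROUP)


@pytest.fixture(scope="module")
def reference_map(rooted_reference, siphini_matrix):
    return map_apomorphies(rooted_reference, siphini_matrix, "acctran")


class TestRooting:
    def test_rooting_then_unrooting_preserves_splits(self, reference_tree):
        rooted = root_on_outgroup(reference_tree, OUTGROUP)
        assert rooted.rooted
        assert unroot(rooted) == reference_tree

    def test_root_children_are_outgroup_and_ingroup(self, rooted_reference):
        kids = rooted_reference.root.children
        assert len(kids) == 2
        labels = {k.label for k in kids}
        assert OUTGROUP in labels

    def test_unknown_outgroup_rejected(self, reference_tree):
        with pytest.raises(MorphocladError):
            root_on_outgroup(reference_tree, "Nosuchia_imaginaria")


class TestReferenceMap:
    def test_total_changes_equal_tree_length(self, reference_map):
        assert reference_map.total_changes == 14

    def test_per_character_conservation(
        self, reference_map, rooted_reference, siphini_matrix
    ):
        steps = per_character_steps(rooted_reference, siphini_matrix)
        for j in range(siphini_matrix.nchar):
            assert len(reference_map.by_character(j)) == steps[j]

    def test_siphunculus_position_reverses_in_laingia(self, reference_map):
        """Character 8 (siphunculus on V): one gain below Caricosipha,
        undone on the Laingia psammae branch."""
        changes = reference_map.by_character(8)
        kinds = sorted(c.classification for c in changes)
        assert kinds == [HOMOPLASIOUS_FORWARD, REVERSAL]
        reversal = next(c for c in changes if c.classification == REVERSAL)
        assert reversal.branch == frozenset(["Laingia_psammae"])
        assert (reversal.from_state, reversal.to_state) == (1, 0)

    def test_short_setae_unique_on_atheroides_stem(self, reference_map):
        """Character 2 (short antennal setae) is gained exactly once, on
        the branch uniting the new species with A. serrulatus."""
        (change,) = reference_map.by_character(2)
        assert change.classification == UNIQUE_FORWARD
        assert change.branch == ATHEROIDES_PAIR

    def test_five_segmented_antenna_subtends_all_siphini(self, reference_map):
        (change,) = reference_map.by_character(1)
        assert change.classification == UNIQUE_FORWARD
        assert len(change.branch) == 9
        assert OUTGROUP not in change.branch

    def test_root_states_are_outgroup_states(self, reference_map):
        assert reference_map.root_states == (0,) * 12


class TestResolutions:
    def test_acctran_deltran_same_per_character_totals(
        self, rooted_reference, siphini_matrix
    ):
        acc = map_apomorphies(rooted_reference, siphini_matrix, "acctran")
        delt = map_apomorphies(rooted_reference, siphini_matrix, "deltran")
        for j in range(siphini_matrix.nchar):
            acc_dirs = sorted(
                (c.from_state, c.to_state) for c in acc.by_character(j)
            )
            delt_dirs = sorted(
                (c.from_state, c.to_state) for c in delt.by_character(j)
            )
            assert len(acc_dirs) == len(delt_dirs)

    def test_unrooted_tree_rejected(self, reference_tree, siphini_matrix):
        with pytest.raises(MorphocladError, match="root"):
            map_apomorphies(reference_tree, siphini_matrix)

    def test_bad_resolution_rejected(self, rooted_reference, siphini_matrix):
        with pytest.raises(MorphocladError):
            map_apomorphies(rooted_reference, siphini_matrix, "midtran")


class TestGeneralProperties:
    def test_constant_character_maps_no_changes(self):
        matrix = CharacterMatrix(
            [Taxon(x) for x in "ABCD"], [[0, 1], [0, 1], [0, 0], [0, 0]]
        )
        from morphoclad import parse_newick

        rooted = root_on_outgroup(parse_newick("(A,B,(C,D));"), "A")
        amap = map_apomorphies(rooted, matrix)
        assert amap.by_character(0) == ()
        assert len(amap.by_character(1)) == 1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("resolution", ["acctran", "deltran"])
    def test_conservation_on_random_trees(self, seed, resolution):
        tree = random_topology([f"t{i}" for i in range(7)], seed)
        matrix = simulate_characters(tree, SimulationConfig(10, 0.25, seed))
        rooted = root_on_outgroup(tree, "t0")
        amap = map_apomorphies(rooted, matrix, resolution)
        steps = per_character_steps(rooted, matrix)
        for j in range(matrix.nchar):
            assert len(amap.by_character(j)) == steps[j]
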