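"""Character coding: threshold scoring, gap handling, ratio mining."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoclad import (
    MissingObservationError,
    SpecimenRecord,
    UNSCORABLE,
    bimodality_screen,
    builtin_definitions,
    builtin_profile,
    generate_specimens,
    mine_ratios,
    score_all,
    score_character,
)
from morphoclad.datamodel import MorphocladError

DEFS = builtin_definitions()


def record(measurements=None, categorical=None):
    return SpecimenRecord(measurements or {}, categorical or {})


class TestThresholdScoring:
    @pytest.mark.parametrize(
        "length,width,expected",
        [
            (2.10, 0.60, 1),        # ratio exactly 3.5: "at least 3.5x"
            (2.40, 0.75, UNSCORABLE),  # 3.2, inside the (3.0, 3.5) gap
            (2.10, 0.75, 0),        # 2.8: "less than 3x"
        ],
    )
    def test_body_elongation(self, length, width, expected):
        rec = record({"body_length": length,
                      "body_width_at_siphunculi": width})
        assert score_character(rec, DEFS[0]) == expected

    @pytest.mark.parametrize(
        "hind,mid,expected",
        [
            (1.55, 1.0, UNSCORABLE),  # inside the (1.5, 1.6) gap
            (1.62, 1.0, 1),
            (1.40, 1.0, 0),
        ],
    )
    def test_femur_ratio(self, hind, mid, expected):
        rec = record({"hindfemur_length": hind, "midfemur_length": mid})
        assert score_character(rec, DEFS[4]) == expected

    @pytest.mark.parametrize(
        "segments,expected", [(6, 0), (5, 1)]
    )
    def test_antennal_segments(self, segments, expected):
        rec = record(categorical={"antennal_segments": segments})
        assert score_character(rec, DEFS[1]) == expected

    def test_four_segments_warns_but_scores_derived(self):
        rec = record(categorical={"antennal_segments": 4})
        with pytest.warns(UserWarning):
            assert score_character(rec, DEFS[1]) == 1

    def test_absent_seta_is_derived_state(self):
        rec = record(categorical={"ant3_apical_seta": "absent"})
        assert score_character(rec, DEFS[2]) == 1

    def test_seta_gap(self):
        rec = record({"ant3_apical_seta_length": 0.024,
                      "ant3_width_mid": 0.020})  # ratio 1.2 in (1.05, 1.3)
        assert score_character(rec, DEFS[2]) is UNSCORABLE

    def test_subequal_boundary_inclusive_for_processus(self):
        rec = record({"processus_terminalis_length": 0.105,
                      "terminal_segment_base_length": 0.100})
        assert score_character(rec, DEFS[3]) == 0

    @given(ratio=st.floats(0.1, 6.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_states_disjoint_over_random_ratios(self, ratio):
        """No ratio can ever satisfy both state predicates."""
        rec = record({"body_length": ratio, "body_width_at_siphunculi": 1.0})
        value = score_character(rec, DEFS[0])
        if ratio < 3.0:
            assert value == 0
        elif ratio >= 3.5:
            assert value == 1
        else:
            assert value is UNSCORABLE

    def test_field_order_irrelevant(self):
        a = record({"hindfemur_length": 0.37, "midfemur_length": 0.21})
        b = record({"midfemur_length": 0.21, "hindfemur_length": 0.37})
        assert score_character(a, DEFS[4]) == score_character(b, DEFS[4])


class TestScoreAll:
    def test_vallescaldera_profile_matches_matrix_row(self, siphini_matrix):
        for rec in generate_specimens(
            builtin_profile("vallescaldera_apterous"), 10, seed=11
        ):
            states = score_all(rec)
            assert list(states) == siphini_matrix.row(
                "Atheroides_vallescaldera"
            ).tolist()

    def test_outgroup_profile_is_all_plesiomorphic(self):
        for rec in generate_specimens(
            builtin_profile("outgroup_apterous"), 10, seed=12
        ):
            assert score_all(rec) == (0,) * 12

    def test_missing_measurement_names_character(self):
        rec = generate_specimens(
            builtin_profile("vallescaldera_apterous"), 1, seed=1
        )[0]
        del rec.measurements["midfemur_length"]
        with pytest.raises(MissingObservationError, match="character 4"):
            score_all(rec)


class TestBimodalityScreen:
    @pytest.mark.parametrize(
        "values,verdict,fraction",
        [
            ([3.5, 3.6, 1.1, 1.2], "bimodal_with_gap", 2.3 / 2.5),
            ([1, 2, 3, 4, 5], "unimodal", 0.25),
            ([7, 7, 7], "unimodal", 0.0),
        ],
    )
    def test_verdicts(self, values, verdict, fraction):
        got, _gap, frac, _boundary = bimodality_screen(values)
        assert got == verdict
        assert frac == pytest.approx(fraction)

    def test_too_few_values(self):
        with pytest.raises(MorphocladError):
            bimodality_screen([1.0, 2.0])

    def test_gap_boundary_reported(self):
        _v, gap, _f, boundary = bimodality_screen([1.0, 1.02, 2.9, 3.0])
        assert gap == pytest.approx(1.88)
        assert boundary == (1.02, 2.9)


class TestMineRatios:
    def test_candidate_count_is_pairs(self):
        per_taxon = {
            f"t{i}": {"a": 1.0 + i, "b": 2.0 + i, "c": 3.0 + i}
            for i in range(4)
        }
        results = mine_ratios(per_taxon)
        assert len(results) == 3  # C(3, 2)
        assert all(r.numerator < r.denominator for r in results)

    def test_gap_found_across_taxa(self):
        per_taxon = {
            "t0": {"a": 1.0, "b": 1.0},
            "t1": {"a": 1.02, "b": 1.0},
            "t2": {"a": 2.9, "b": 1.0},
            "t3": {"a": 3.0, "b": 1.0},
        }
        (result,) = mine_ratios(per_taxon)
        assert result.verdict == "bimodal_with_gap"
        assert result.boundary == (1.02, 2.9)

    def test_zero_denominator_flags_taxon(self):
        per_taxon = {
            "t0": {"a": 1.0, "b": 0.0},
            "t1": {"a": 2.0, "b": 1.0},
            "t2": {"a": 3.0, "b": 1.0},
            "t3": {"a": 4.0, "b": 1.0},
        }
        (result,) = mine_ratios(per_taxon)
        assert result.skipped == ("t0",)
        assert set(result.values) == {"t1", "t2", "t3"}

    def test_mismatched_measurements_rejected(self):
        with pytest.raises(MorphocladError):
            mine_ratios({"t0": {"a": 1.0}, "t1": {"b": 1.0}})
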