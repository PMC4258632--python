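"""Dichotomous-key engine: descent, validation, boundary behaviour."""

import pytest

from morphoclad import (
    Key,
    MissingObservationError,
    SpecimenRecord,
    builtin_key,
    builtin_profile,
    generate_specimens,
    identify,
    validate_key,
)
from morphoclad.keys import KeyCouplet, Lead


def ovipara_record(pseudosensoria, shape="acuminate", empodia="parallel_sided",
                   marginal=0.07, femur_width=0.055):
    return SpecimenRecord(
        measurements={
            "marginal_seta_length": marginal,
            "hindfemur_width_mid": femur_width,
        },
        categorical={
            "pseudosensoria_per_hindtibia": pseudosensoria,
            "marginal_seta_shape": shape,
            "empodial_setae": empodia,
        },
    )


class TestOviparaKey:
    def test_low_count_acuminate_keys_to_new_species(self):
        result = identify(ovipara_record(22), "ovipara_na")
        assert result.species == "vallescaldera"
        assert [s.couplet for s in result.trace] == ["1"]

    def test_high_count_spatulate_keys_to_serrulatus(self):
        record = ovipara_record(35, shape="dentate", empodia="spatulate",
                                marginal=0.03)
        assert identify(record, "ovipara_na").species == "serrulatus"

    def test_exactly_thirty_is_indeterminate(self):
        """'More than 30' and 'less than 30' are both false at 30."""
        result = identify(ovipara_record(30), "ovipara_na")
        assert result.indeterminate
        assert result.conflict_couplet == "1"

    def test_generated_specimens_always_key_correctly(self):
        for rec in generate_specimens(
            builtin_profile("vallescaldera_ovipara"), 25, seed=7
        ):
            assert identify(rec, "ovipara_na").species == "vallescaldera"
        for rec in generate_specimens(
            builtin_profile("serrulatus_ovipara"), 25, seed=8
        ):
            assert identify(rec, "ovipara_na").species == "serrulatus"


class TestApterousKey:
    def test_doncasteri_path(self):
        record = SpecimenRecord(
            measurements={
                "spinal_seta_length": 0.08,
                "marginal_seta_length": 0.08,
            },
            categorical={
                "dorsal_seta_shapes": ("acuminate",),
                "tergite8_covers_cauda": True,
            },
        )
        result = identify(record, "apterous")
        assert result.species == "doncasteri"
        assert [s.couplet for s in result.trace] == ["1", "2"]

    def test_vallescaldera_path(self):
        record = generate_specimens(
            builtin_profile("vallescaldera_apterous"), 1, seed=3
        )[0]
        result = identify(record, "apterous")
        assert result.species == "vallescaldera"
        assert [s.couplet for s in result.trace] == ["1", "3", "4", "5"]

    def test_marginal_equal_to_femur_width_is_indeterminate(self):
        """A specimen sitting exactly on the couplet-5 length comparison
        matches neither lead."""
        record = generate_specimens(
            builtin_profile("vallescaldera_apterous"), 1, seed=3
        )[0]
        record.measurements["marginal_seta_length"] = 0.055
        record.measurements["hindfemur_width_mid"] = 0.055
        result = identify(record, "apterous")
        assert result.indeterminate
        assert result.conflict_couplet == "5"

    def test_missing_trait_names_couplet(self):
        record = SpecimenRecord(
            categorical={"dorsal_seta_shapes": ("acuminate",)}
        )
        with pytest.raises(MissingObservationError, match="couplet 2"):
            identify(record, "apterous")

    def test_identify_is_pure(self):
        record = generate_specimens(
            builtin_profile("vallescaldera_apterous"), 1, seed=9
        )[0]
        assert identify(record, "apterous") == identify(record, "apterous")


class TestValidation:
    def test_apterous_key_structure(self):
        report = validate_key("apterous")
        assert report.ok
        assert report.n_couplets == 6
        assert report.terminals == (
            "brevicornis", "doncasteri", "hirtellus", "karakumi",
            "persianus", "serrulatus", "vallescaldera",
        )

    def test_ovipara_key_structure(self):
        report = validate_key("ovipara_na")
        assert report.ok
        assert report.terminals == ("serrulatus", "vallescaldera")

    def test_dangling_target_reported(self):
        broken = Key("broken", {
            "1": KeyCouplet("1", (
                Lead("1", "a", lambda r: True, "2"),   # couplet 2 missing
                Lead("1'", "b", lambda r: False, "speciesx"),
            )),
        })
        report = validate_key(broken)
        assert not report.ok
        assert any("missing couplet" in v for v in report.violations)

    def test_cycle_reported(self):
        looping = Key("loop", {
            "1": KeyCouplet("1", (
                Lead("1", "a", lambda r: True, "2"),
                Lead("1'", "b", lambda r: False, "sp1"),
            )),
            "2": KeyCouplet("2", (
                Lead("2", "a", lambda r: True, "1"),
                Lead("2'", "b", lambda r: False, "sp2"),
            )),
        })
        report = validate_key(looping)
        assert any("cycle" in v for v in report.violations)
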