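"""Morphometric character coding and the ratio-mining screen.

The twelve built-in binary characters translate raw specimen observations
(ratios of body measurements, counts, shape classes) into the matrix
states used by the cladistic analysis.  Ratio characters carry an
explicit *gap*: the open interval between the state-0 and state-1
thresholds, inside which a specimen is unscorable rather than forced into
a state (ambiguity is a first-class outcome, mirroring the removal of
characters that could not be scored unambiguously).

The mining utilities reproduce the discovery procedure: compute every
pairwise ratio of a measurement set across taxa and screen each ratio's
distribution for a clear gap (a stand-in for visual histogram
inspection): a distribution is called bimodal-with-gap when the largest
gap between consecutive sorted values is at least ``gap_fraction`` of the
total range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .datamodel import MorphocladError, SpecimenRecord

#: Returned by scorers when the observation falls in a definition's gap.
UNSCORABLE = None

#: "subequal" (e.g. seta length vs segment width) operationalised as a
#: ratio of at most this value; the printed descriptions never quantify it.
DEFAULT_SUBEQUAL_TOLERANCE = 1.05

#: Largest-gap fraction above which a ratio distribution is called bimodal.
DEFAULT_GAP_FRACTION = 0.35


class MissingObservationError(MorphocladError):
    """A required measurement or trait is absent from a specimen record."""

    def __init__(self, name: str, context: str = "") -> None:
        self.name = name
        suffix = f" ({context})" if context else ""
        super().__init__(f"record is missing required field {name!r}{suffix}")


def _measure(record: SpecimenRecord, name: str) -> float:
    try:
        return float(record.measurements[name])
    except KeyError:
        raise MissingObservationError(name) from None


def _trait(record: SpecimenRecord, name: str):
    try:
        return record.categorical[name]
    except KeyError:
        raise MissingObservationError(name) from None


@dataclass(frozen=True)
class CharacterDefinition:
    """One binary character: index, kind and a scoring predicate.

    ``scorer`` returns 0, 1 or :data:`UNSCORABLE`; ``requires`` names the
    record fields the scorer reads (used for validation and error
    messages); ``gap`` describes the unscorable interval of a ratio
    character, when one exists.
    """

    index: int
    label: str
    kind: str  # ratio_threshold | count | categorical
    requires: tuple[str, ...]
    scorer: Callable[[SpecimenRecord], Optional[int]]
    gap: Optional[tuple[float, float]] = None

    def score(self, record: SpecimenRecord) -> Optional[int]:
        return self.scorer(record)


def _ratio_definition(
    index: int, label: str, numerator: str, denominator: str,
    *, state0_max: float = None, state0_min: float = None,
    state1_min: float = None, state1_max: float = None,
    state0_max_inclusive: bool = False,
    absent_numerator_state: Optional[int] = None,
    absence_trait: Optional[str] = None,
) -> CharacterDefinition:
    """Build a two-threshold ratio character.

    Exactly one of the state-0 bounds and one of the state-1 bounds is
    given; the unscorable gap is whatever lies between them.
    """
    if state0_max is not None and state1_min is not None:
        gap = (state0_max, state1_min)       # state0 low, state1 high
    elif state1_max is not None and state0_min is not None:
        gap = (state1_max, state0_min)       # state1 low, state0 high
    else:
        raise MorphocladError("ratio character needs one bound per state")

    # Thresholds follow the character wording: "less than" is strict,
    # "at least" inclusive, "subequal or less" inclusive.
    def scorer(record: SpecimenRecord) -> Optional[int]:
        if absence_trait is not None and absent_numerator_state is not None:
            if record.categorical.get(absence_trait) == "absent":
                return absent_numerator_state
        num = _measure(record, numerator)
        den = _measure(record, denominator)
        ratio = num / den
        if state0_max is not None:
            if ratio < state0_max or (state0_max_inclusive
                                      and ratio == state0_max):
                return 0
            if ratio >= state1_min:
                return 1
            return UNSCORABLE
        if ratio <= state1_max:
            return 1
        if ratio >= state0_min:
            return 0
        return UNSCORABLE

    return CharacterDefinition(
        index=index,
        label=label,
        kind="ratio_threshold",
        requires=(numerator, denominator),
        scorer=scorer,
        gap=gap,
    )


def builtin_definitions(
    subequal_tolerance: float = DEFAULT_SUBEQUAL_TOLERANCE,
) -> tuple[CharacterDefinition, ...]:
    """The twelve built-in character definitions.

    ``subequal_tolerance`` sets the ratio treated as "subequal" in
    characters 2 and 3.
    """
    t = float(subequal_tolerance)

    def c1_antennal_segments(record: SpecimenRecord) -> Optional[int]:
        n = _trait(record, "antennal_segments")
        if n == 6:
            return 0
        if n == 5:
            return 1
        if isinstance(n, int) and n < 5:
            warnings.warn(
                f"antenna with {n} segments coded as state 1 (five); the "
                "matrix only distinguishes six vs five", stacklevel=2,
            )
            return 1
        return UNSCORABLE

    def c5_seta_shape(record: SpecimenRecord) -> Optional[int]:
        shapes = set(_trait(record, "dorsal_seta_shapes"))
        derived = {"scale_like", "denticulate", "dentate", "flabellate"}
        if shapes & derived:
            return 1
        if shapes <= {"acuminate"} and shapes:
            return 0
        return UNSCORABLE

    def c8_siphunculus_segment(record: SpecimenRecord) -> Optional[int]:
        seg = _trait(record, "siphunculus_segment")
        if seg == 6:
            return 0
        if seg == 5:
            return 1
        return UNSCORABLE

    def c9_orifice(record: SpecimenRecord) -> Optional[int]:
        level = _trait(record, "siphunculus_orifice")
        if level == "tube":
            return 0
        if level in ("flush", "mound"):
            return 1
        return UNSCORABLE

    def c10_tergite8(record: SpecimenRecord) -> Optional[int]:
        return 1 if _trait(record, "tergite8_covers_cauda") else 0

    def c11_cauda(record: SpecimenRecord) -> Optional[int]:
        level = _trait(record, "cauda_shape")
        if level == "knobbed":
            return 0
        if level in ("rounded", "truncate", "emarginate"):
            return 1
        return UNSCORABLE

    def categorical(index, label, requires, fn):
        return CharacterDefinition(index, label, "categorical",
                                   tuple(requires), fn)

    return (
        _ratio_definition(
            0, "body elongation (length / width at siphunculi)",
            "body_length", "body_width_at_siphunculi",
            state0_max=3.0, state1_min=3.5,
        ),
        categorical(
            1, "antennal segment number (six vs five)",
            ("antennal_segments",), c1_antennal_segments,
        ),
        _ratio_definition(
            2, "dorsal apical seta of antennal III / segment width",
            "ant3_apical_seta_length", "ant3_width_mid",
            state1_max=t, state0_min=1.3,
            absent_numerator_state=1, absence_trait="ant3_apical_seta",
        ),
        _ratio_definition(
            3, "processus terminalis / base of terminal antennal segment",
            "processus_terminalis_length", "terminal_segment_base_length",
            state0_max=t, state1_min=1.5, state0_max_inclusive=True,
        ),
        _ratio_definition(
            4, "hindfemur length / midfemur length",
            "hindfemur_length", "midfemur_length",
            state0_max=1.5, state1_min=1.6,
        ),
        categorical(
            5, "dorsal seta shape",
            ("dorsal_seta_shapes",), c5_seta_shape,
        ),
        categorical(
            6, "denticulate/spiculate cuticle over most of body",
            ("cuticle_denticulate",),
            lambda r: 1 if _trait(r, "cuticle_denticulate") else 0,
        ),
        categorical(
            7, "dorsal cuticular wrinkles and folds",
            ("dorsal_wrinkles",),
            lambda r: 1 if _trait(r, "dorsal_wrinkles") else 0,
        ),
        categorical(
            8, "siphunculus base on segment VI (0) vs V (1)",
            ("siphunculus_segment",), c8_siphunculus_segment,
        ),
        categorical(
            9, "siphunculus orifice on a tube (0) vs flush/mound (1)",
            ("siphunculus_orifice",), c9_orifice,
        ),
        categorical(
            10, "tergite VIII expanded, hiding the cauda",
            ("tergite8_covers_cauda",), c10_tergite8,
        ),
        categorical(
            11, "cauda knobbed (0) vs broadly rounded/truncate/emarginate (1)",
            ("cauda_shape",), c11_cauda,
        ),
    )


def score_character(
    record: SpecimenRecord, definition: CharacterDefinition
) -> Optional[int]:
    """Score one character on one specimen; UNSCORABLE inside the gap."""
    return definition.score(record)


def score_all(
    record: SpecimenRecord,
    definitions: Optional[Sequence[CharacterDefinition]] = None,
) -> tuple[Optional[int], ...]:
    """Score all (by default the twelve built-in) characters.

    Missing-field errors are re-raised with the character index attached.
    """
    if definitions is None:
        definitions = builtin_definitions()
    states = []
    for defn in definitions:
        try:
            states.append(defn.score(record))
        except MissingObservationError as exc:
            raise MissingObservationError(
                exc.name, f"required by character {defn.index}"
            ) from exc
    return tuple(states)


# ---------------------------------------------------------------------------
# Ratio mining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatioScreenResult:
    """Bimodality screen of one measurement ratio across taxa."""

    numerator: str
    denominator: str
    values: dict[str, float]        # per taxon
    skipped: tuple[str, ...]        # taxa with a zero denominator
    verdict: str                    # unimodal | bimodal_with_gap
    largest_gap: float
    gap_fraction: float
    boundary: Optional[tuple[float, float]]  # (low-cluster max, high-cluster min)


def bimodality_screen(
    values: Sequence[float], gap_fraction: float = DEFAULT_GAP_FRACTION
) -> tuple[str, float, float, Optional[tuple[float, float]]]:
    """Largest-gap bimodality rule on >= 3 finite values.

    Returns (verdict, largest gap, gap/range fraction, cluster boundary).
    The verdict is ``bimodal_with_gap`` iff the largest gap between
    consecutive sorted values is at least ``gap_fraction`` of the total
    range (so each side holds at least one value by construction).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 3:
        raise MorphocladError("bimodality screen needs at least 3 values")
    if not np.isfinite(vals).all():
        raise MorphocladError("bimodality screen needs finite values")
    vals.sort()
    rng = float(vals[-1] - vals[0])
    if rng == 0.0:
        return ("unimodal", 0.0, 0.0, None)
    diffs = np.diff(vals)
    i = int(np.argmax(diffs))
    gap = float(diffs[i])
    frac = gap / rng
    if frac >= gap_fraction:
        return ("bimodal_with_gap", gap, frac, (float(vals[i]), float(vals[i + 1])))
    return ("unimodal", gap, frac, None)


def mine_ratios(
    measurements: Mapping[str, Mapping[str, float]],
    gap_fraction: float = DEFAULT_GAP_FRACTION,
) -> list[RatioScreenResult]:
    """Screen every pairwise measurement ratio across taxa.

    ``measurements`` maps taxon -> {measurement name -> value}; every
    taxon must carry the same measurement names.  Ratios are oriented
    with the lexically smaller name as numerator; a taxon with a zero
    denominator is flagged and skipped for that ratio.
    """
    taxa = list(measurements)
    if len(taxa) < 2:
        raise MorphocladError("ratio mining needs at least 2 taxa")
    names = sorted(measurements[taxa[0]])
    for taxon in taxa:
        if sorted(measurements[taxon]) != names:
            raise MorphocladError(
                f"taxon {taxon!r} has a different measurement list"
            )
    out = []
    for num, den in combinations(names, 2):
        values: dict[str, float] = {}
        skipped: list[str] = []
        for taxon in taxa:
            d = float(measurements[taxon][den])
            if d == 0.0:
                skipped.append(taxon)
                continue
            values[taxon] = float(measurements[taxon][num]) / d
        verdict, gap, frac, boundary = (
            bimodality_screen(list(values.values()), gap_fraction)
            if len(values) >= 3
            else ("unimodal", 0.0, 0.0, None)
        )
        out.append(
            RatioScreenResult(
                numerator=num,
                denominator=den,
                values=values,
                skipped=tuple(skipped),
                verdict=verdict,
                largest_gap=gap,
                gap_fraction=frac,
                boundary=boundary,
            )
        )
    return out
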