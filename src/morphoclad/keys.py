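"""Executable dichotomous identification keys for *Atheroides*.

Two built-in keys are shipped: the seven-species key to apterous
viviparae and the two-species key to North American oviparae (separated
by pseudosensoria counts on the hind tibiae).  Each couplet holds two
leads, each a predicate over a :class:`SpecimenRecord` plus a target
(another couplet or a terminal species).  Identification descends from
couplet 1 and records a full trace; when neither or both leads of a
couplet hold (e.g. exactly 30 pseudosensoria, where the leads read
"more than 30" and "less than 30"), the result is *indeterminate* rather
than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .coding import MissingObservationError, builtin_definitions
from .datamodel import MorphocladError, SpecimenRecord

APTEROUS = "apterous"
OVIPARA_NA = "ovipara_na"


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
class Lead:
    """One lead of a couplet: its printed gist, predicate and target."""

    label: str                 # e.g. "1" or "1'"
    text: str
    predicate: Callable[[SpecimenRecord], bool]
    target: str                # couplet id or terminal species name


@dataclass(frozen=True)
class KeyCouplet:
    id: str
    leads: tuple[Lead, Lead]


@dataclass(frozen=True)
class Key:
    name: str
    couplets: dict[str, KeyCouplet]
    start: str = "1"

    def is_terminal(self, target: str) -> bool:
        """Numeric targets refer to couplets; anything else is a species."""
        return target not in self.couplets and not target.isdigit()


@dataclass(frozen=True)
class TraceStep:
    couplet: str
    first_holds: bool
    second_holds: bool
    chosen: Optional[str]      # lead label, None when indeterminate


@dataclass(frozen=True)
class KeyResult:
    species: Optional[str]
    trace: tuple[TraceStep, ...]

    @property
    def indeterminate(self) -> bool:
        return self.species is None

    @property
    def conflict_couplet(self) -> Optional[str]:
        if self.species is not None:
            return None
        return self.trace[-1].couplet if self.trace else None


# ---------------------------------------------------------------------------
# Built-in keys
# ---------------------------------------------------------------------------

# The dorsal-seta shape discrimination of couplet 1 reuses the character-5
# scorer so the key and the matrix coding cannot drift apart.
_CHAR5 = builtin_definitions()[5]


def _setae_exclusively_acuminate(r: SpecimenRecord) -> bool:
    return _CHAR5.score(r) == 0


def _setae_not_exclusively_acuminate(r: SpecimenRecord) -> bool:
    return _CHAR5.score(r) == 1


def _marginal_longer_than_hindfemur_width(r: SpecimenRecord) -> bool:
    return (_measure(r, "marginal_seta_length")
            > _measure(r, "hindfemur_width_mid"))


def _marginal_shorter_than_hindfemur_width(r: SpecimenRecord) -> bool:
    return (_measure(r, "marginal_seta_length")
            < _measure(r, "hindfemur_width_mid"))


def _build_apterous_key() -> Key:
    couplets = {}

    couplets["1"] = KeyCouplet("1", (
        Lead("1", "setae on the dorsum exclusively acuminate",
             _setae_exclusively_acuminate, "2"),
        Lead("1'", "dorsal setae acuminate, forked, dentate and/or flabellate",
             _setae_not_exclusively_acuminate, "3"),
    ))
    couplets["2"] = KeyCouplet("2", (
        Lead("2", "spinal setae as long as or longer than marginal; "
                  "cauda covered by tergite VIII",
             lambda r: (_measure(r, "spinal_seta_length")
                        >= _measure(r, "marginal_seta_length"))
             and bool(_trait(r, "tergite8_covers_cauda")),
             "doncasteri"),
        Lead("2'", "marginal setae longer than spinal; cauda not covered",
             lambda r: (_measure(r, "marginal_seta_length")
                        > _measure(r, "spinal_seta_length"))
             and not _trait(r, "tergite8_covers_cauda"),
             "hirtellus"),
    ))
    # NOTE: the printed key heads this couplet "3 (2')" although it is
    # reached from lead 1'; the lead targets define the graph, so the
    # provenance tag is treated as a typographical slip.
    couplets["3"] = KeyCouplet("3", (
        Lead("3", "dorsum partially sclerotic without visible sculpture; "
                  "antennal III with 4-8 long setae",
             lambda r: _trait(r, "dorsum_sculpture") == "none"
             and _trait(r, "ant3_seta_count") >= 4,
             "karakumi"),
        Lead("3'", "dorsum sclerotic with rugose sculpture; "
                   "antennal III with 0-4 short setae",
             lambda r: _trait(r, "dorsum_sculpture") == "rugose"
             and _trait(r, "ant3_seta_count") <= 4,
             "4"),
    ))
    couplets["4"] = KeyCouplet("4", (
        Lead("4", "dorsal setae arranged in visible rows",
             lambda r: bool(_trait(r, "dorsal_setae_in_rows")), "5"),
        Lead("4'", "dorsal setae not arranged in visible rows",
             lambda r: not _trait(r, "dorsal_setae_in_rows"), "6"),
    ))
    couplets["5"] = KeyCouplet("5", (
        Lead("5", "marginal setae short, hardly visible, rarely as long as "
                  "hindfemur width, dentate; empodial setae spatulate",
             lambda r: _marginal_shorter_than_hindfemur_width(r)
             and _trait(r, "marginal_seta_shape") == "dentate"
             and _trait(r, "empodial_setae") == "spatulate",
             "serrulatus"),
        Lead("5'", "marginal setae easily visible, longer than hindfemur "
                   "width at middle, acuminate; empodial setae of equal "
                   "basal and apical width, not spatulate",
             lambda r: _marginal_longer_than_hindfemur_width(r)
             and _trait(r, "marginal_seta_shape") == "acuminate"
             and _trait(r, "empodial_setae") != "spatulate",
             "vallescaldera"),
    ))
    couplets["6"] = KeyCouplet("6", (
        Lead("6", "body oval, 1.50-2.40 mm; antennae 4- or 5-segmented, "
                  "0.12-0.15 x body",
             lambda r: 1.50 <= _measure(r, "body_length") <= 2.40
             and _trait(r, "antennal_segments") in (4, 5)
             and 0.12 <= (_measure(r, "antenna_length")
                          / _measure(r, "body_length")) <= 0.15,
             "brevicornis"),
        Lead("6'", "body slender, nearly linear, 1.55-1.72 mm; antennae "
                   "5-segmented, 0.18-0.25 x body",
             lambda r: 1.55 <= _measure(r, "body_length") <= 1.72
             and _trait(r, "antennal_segments") == 5
             and 0.18 <= (_measure(r, "antenna_length")
                          / _measure(r, "body_length")) <= 0.25,
             "persianus"),
    ))
    return Key(APTEROUS, couplets)


def _build_ovipara_key() -> Key:
    couplets = {
        "1": KeyCouplet("1", (
            Lead("1", "hind tibiae with more than 30 pseudosensoria; "
                      "marginal setae short, dentate; empodial setae "
                      "spatulate",
                 lambda r: _trait(r, "pseudosensoria_per_hindtibia") > 30
                 and _trait(r, "marginal_seta_shape") == "dentate"
                 and _trait(r, "empodial_setae") == "spatulate",
                 "serrulatus"),
            Lead("1'", "hind tibiae with less than 30 pseudosensoria; "
                       "marginal setae longer than hindfemur width, "
                       "acuminate; empodial setae not spatulate",
                 lambda r: _trait(r, "pseudosensoria_per_hindtibia") < 30
                 and _trait(r, "marginal_seta_shape") == "acuminate"
                 and _trait(r, "empodial_setae") != "spatulate",
                 "vallescaldera"),
        )),
    }
    return Key(OVIPARA_NA, couplets)


_BUILTIN: dict[str, Key] = {}


def builtin_key(name: str) -> Key:
    if not _BUILTIN:
        _BUILTIN[APTEROUS] = _build_apterous_key()
        _BUILTIN[OVIPARA_NA] = _build_ovipara_key()
    try:
        return _BUILTIN[name]
    except KeyError:
        raise MorphocladError(
            f"unknown key {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def identify(record: SpecimenRecord, key: Key | str) -> KeyResult:
    """Run a specimen down a key; deterministic, with a full trace.

    Raises :class:`MissingObservationError` (naming trait and couplet)
    when a visited couplet needs a field the record lacks.
    """
    if isinstance(key, str):
        key = builtin_key(key)
    trace: list[TraceStep] = []
    current = key.start
    for _ in range(len(key.couplets) + 1):
        couplet = key.couplets[current]
        first, second = couplet.leads
        try:
            holds1 = bool(first.predicate(record))
            holds2 = bool(second.predicate(record))
        except MissingObservationError as exc:
            raise MissingObservationError(
                exc.name, f"needed at couplet {couplet.id} of the "
                f"{key.name} key"
            ) from exc
        if holds1 == holds2:  # neither or both: no unambiguous lead
            trace.append(TraceStep(couplet.id, holds1, holds2, None))
            return KeyResult(None, tuple(trace))
        chosen = first if holds1 else second
        trace.append(TraceStep(couplet.id, holds1, holds2, chosen.label))
        if key.is_terminal(chosen.target):
            return KeyResult(chosen.target, tuple(trace))
        if chosen.target not in key.couplets:
            raise MorphocladError(
                f"key {key.name!r}: lead {chosen.label} targets missing "
                f"couplet {chosen.target!r}"
            )
        current = chosen.target
    raise MorphocladError(f"key {key.name!r} descent did not terminate "
                          "(cycle in couplet targets)")


@dataclass(frozen=True)
class KeyReport:
    key: str
    n_couplets: int
    terminals: tuple[str, ...]
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_key(key: Key | str) -> KeyReport:
    """Structural validation: targets resolve, the couplet graph is
    acyclic and fully reachable, and every terminal appears once."""
    if isinstance(key, str):
        key = builtin_key(key)
    violations: list[str] = []
    terminals: list[str] = []
    if key.start not in key.couplets:
        violations.append(f"start couplet {key.start!r} missing")

    # reachability + acyclicity over the couplet graph
    seen: set[str] = set()
    stack = [key.start] if key.start in key.couplets else []
    order: list[str] = []
    while stack:
        cid = stack.pop()
        if cid in seen:
            continue
        seen.add(cid)
        order.append(cid)
        for lead in key.couplets[cid].leads:
            if key.is_terminal(lead.target):
                terminals.append(lead.target)
            else:
                if lead.target not in key.couplets:
                    violations.append(
                        f"lead {lead.label} targets missing couplet "
                        f"{lead.target!r}"
                    )
                else:
                    stack.append(lead.target)
    unreachable = sorted(set(key.couplets) - seen)
    if unreachable:
        violations.append(f"unreachable couplets: {unreachable}")
    # cycles: a couplet id reachable from itself
    for cid in key.couplets:
        frontier = [
            l.target for l in key.couplets[cid].leads
            if not key.is_terminal(l.target)
        ]
        visited: set[str] = set()
        while frontier:
            nxt = frontier.pop()
            if nxt == cid:
                violations.append(f"cycle through couplet {cid!r}")
                frontier = []
                break
            if nxt in visited or nxt not in key.couplets:
                continue
            visited.add(nxt)
            frontier.extend(
                l.target for l in key.couplets[nxt].leads
                if not key.is_terminal(l.target)
            )
    dupes = sorted({t for t in terminals if terminals.count(t) > 1})
    if dupes:
        violations.append(f"terminals reached more than once: {dupes}")
    return KeyReport(
        key=key.name,
        n_couplets=len(key.couplets),
        terminals=tuple(sorted(set(terminals))),
        violations=tuple(violations),
    )
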