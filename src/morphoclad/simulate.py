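"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`simulate_characters` — binary characters evolved independently
  on a known tree under a symmetric per-branch change model (each
  character flips state along each branch with probability p < 0.5,
  starting from state 0 at the root).  This is the simplest model whose
  parsimony-consistency regime (small p) is well understood, and matches
  the topology-only trees the analysis works with.
* :func:`generate_specimens` — morphometric specimen records drawn
  uniformly from species-specific measurement ranges (published ranges
  where available), used to exercise character coding and the
  identification keys.

Both are byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    CharacterMatrix,
    CharacterMeta,
    MorphocladError,
    Node,
    PhyloTree,
    SpecimenRecord,
    Taxon,
    canonical_label,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for binary-character simulation on a fixed tree.

    ``keep`` controls which simulated columns enter the matrix:

    * ``"all"`` — every column, constant ones included (the raw model);
    * ``"variable"`` — only columns where both states occur;
    * ``"informative"`` — only parsimony-informative columns (each state
      in at least two taxa).  This emulates an assembled morphological
      matrix, where only characters that vary informatively among the
      taxa are ever coded; it is the regime used by the topology-recovery
      studies.
    """

    n_characters: int = 100
    change_probability: float = 0.05
    seed: int = 0
    keep: str = "all"

    def __post_init__(self) -> None:
        if self.n_characters < 1:
            raise MorphocladError("n_characters must be >= 1")
        if not (0.0 <= self.change_probability < 0.5):
            raise MorphocladError(
                "change_probability must lie in [0, 0.5) for the symmetric "
                f"model, got {self.change_probability}"
            )
        if self.keep not in ("all", "variable", "informative"):
            raise MorphocladError(
                f"keep must be 'all', 'variable' or 'informative', "
                f"got {self.keep!r}"
            )


def random_topology(leaf_labels: Sequence[str],
                    seed: int | np.random.Generator = 0) -> PhyloTree:
    """A uniformly random unrooted binary topology, built by inserting
    each successive leaf onto a uniformly chosen edge."""
    labels = [canonical_label(x) for x in leaf_labels]
    if len(labels) < 3:
        raise MorphocladError("need at least 3 leaves for a topology")
    if len(set(labels)) != len(labels):
        raise MorphocladError("leaf labels must be unique")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    order = list(rng.permutation(len(labels)))
    nodes = [Node(labels[i]) for i in order[:3]]
    root = Node(None, nodes)
    # edges as (parent, child) pairs reachable from the root
    edges: list[tuple[Node, Node]] = [(root, c) for c in nodes]
    for i in order[3:]:
        parent, child = edges[int(rng.integers(len(edges)))]
        leaf = Node(labels[i])
        joint = Node(None, [child, leaf])
        parent.children[parent.children.index(child)] = joint
        edges.remove((parent, child))
        edges.extend([(parent, joint), (joint, child), (joint, leaf)])
    return PhyloTree(root, rooted=False)


def simulate_characters(
    tree: PhyloTree, config: SimulationConfig = SimulationConfig()
) -> CharacterMatrix:
    """Evolve binary characters on ``tree`` under the per-branch flip model.

    The tree's storage root carries state 0 for every character; each
    character then flips independently along each branch with
    probability ``config.change_probability``.  Taxon order in the
    returned matrix follows the tree's leaf order.  With ``keep`` other
    than "all", simulation continues until ``n_characters`` qualifying
    columns have accumulated (a guard trips when the acceptance rate is
    hopeless, e.g. conditioning with p = 0).
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_characters
    p = config.change_probability
    if tree.root.is_leaf:
        raise MorphocladError("simulation tree root must be internal")
    labels = tree.leaf_labels()
    n = len(labels)

    def draw_block(size: int) -> np.ndarray:
        states: dict[str, np.ndarray] = {}

        def walk(v: Node, state: np.ndarray) -> None:
            for child in v.children:
                flips = rng.random(size) < p
                child_state = np.where(flips, 1 - state, state)
                if child.is_leaf:
                    states[child.label] = child_state
                else:
                    walk(child, child_state)

        walk(tree.root, np.zeros(size, dtype=np.int8))
        return np.stack([states[l] for l in labels]).astype(np.int8)

    if config.keep == "all":
        grid = draw_block(k)
    else:
        min_minority = 1 if config.keep == "variable" else 2
        kept: list[np.ndarray] = []
        attempts = 0
        while sum(b.shape[1] for b in kept) < k:
            attempts += 1
            if attempts > 1000:
                raise MorphocladError(
                    f"conditioning keep={config.keep!r} accepts too few "
                    f"columns at p={p}; raise p or use keep='all'"
                )
            block = draw_block(k)
            ones = block.sum(axis=0)
            ok = np.minimum(ones, n - ones) >= min_minority
            if ok.any():
                kept.append(block[:, ok])
        grid = np.concatenate(kept, axis=1)[:, :k]
    characters = [CharacterMeta(j, f"simulated character {j}") for j in range(k)]
    return CharacterMatrix([Taxon(l) for l in labels], grid, characters)


# ---------------------------------------------------------------------------
# Specimen generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species ranges and trait levels for specimen generation.

    ``measurements`` maps names to (min, max) in mm; ``integer_traits``
    to inclusive integer (min, max) ranges; ``categorical`` holds fixed
    trait levels copied onto every record.
    """

    name: str
    measurements: dict[str, tuple[float, float]] = field(default_factory=dict)
    integer_traits: dict[str, tuple[int, int]] = field(default_factory=dict)
    categorical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (lo, hi) in {**self.measurements,
                                **self.integer_traits}.items():
            if lo > hi:
                raise MorphocladError(
                    f"profile {self.name!r}: range for {label!r} has "
                    f"min {lo} > max {hi}"
                )


def generate_specimens(profile: SpeciesProfile, n: int,
                       seed: int = 0) -> list[SpecimenRecord]:
    """Draw ``n`` specimen records uniformly from a species profile."""
    if n < 0:
        raise MorphocladError("specimen count must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        measurements = {
            name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in sorted(profile.measurements.items())
        }
        categorical: dict[str, object] = dict(profile.categorical)
        for name, (lo, hi) in sorted(profile.integer_traits.items()):
            categorical[name] = int(rng.integers(lo, hi + 1))
        out.append(SpecimenRecord(measurements, categorical))
    return out


# Shared trait levels of *A. vallescaldera* (both morphs): flabellate and
# dentate dorsal setae in rows over a rugose dorsum, siphunculus flush on
# segment V, tergite VIII covering the rounded cauda, empodial setae of
# equal basal/apical width (not spatulate).
_VALLESCALDERA_TRAITS: dict[str, object] = {
    "antennal_segments": 5,
    "dorsal_seta_shapes": ("dentate", "flabellate", "acuminate"),
    "dorsum_sculpture": "rugose",
    "ant3_seta_count": 2,
    "dorsal_setae_in_rows": True,
    "marginal_seta_shape": "acuminate",
    "empodial_setae": "parallel_sided",
    "cuticle_denticulate": True,
    "dorsal_wrinkles": True,
    "siphunculus_segment": 5,
    "siphunculus_orifice": "flush",
    "tergite8_covers_cauda": True,
    "cauda_shape": "rounded",
}

# Measurement ranges: published where available (body, antenna, femora,
# processus terminalis); widths and seta lengths chosen inside the
# species' diagnostic ratio regions where no range is printed.
_VALLESCALDERA_MEASUREMENTS: dict[str, tuple[float, float]] = {
    "body_length": (2.07, 2.21),
    "body_width_at_siphunculi": (0.50, 0.55),
    "antenna_length": (0.53, 0.55),
    "ant3_apical_seta_length": (0.010, 0.015),
    "ant3_width_mid": (0.020, 0.022),
    "processus_terminalis_length": (0.075, 0.082),
    "terminal_segment_base_length": (0.080, 0.085),
    "hindfemur_length": (0.365, 0.375),
    "midfemur_length": (0.210, 0.225),
    "hindfemur_width_mid": (0.050, 0.060),
    "marginal_seta_length": (0.062, 0.070),
    "spinal_seta_length": (0.020, 0.040),
}


def builtin_profiles() -> dict[str, SpeciesProfile]:
    """Built-in species profiles for specimen generation."""
    vallescaldera_apterous = SpeciesProfile(
        name="vallescaldera_apterous",
        measurements=dict(_VALLESCALDERA_MEASUREMENTS),
        categorical=dict(_VALLESCALDERA_TRAITS),
    )
    ovipara_measurements = dict(_VALLESCALDERA_MEASUREMENTS)
    ovipara_measurements["body_length"] = (2.08, 2.30)
    vallescaldera_ovipara = SpeciesProfile(
        name="vallescaldera_ovipara",
        measurements=ovipara_measurements,
        integer_traits={"pseudosensoria_per_hindtibia": (18, 27)},
        categorical=dict(_VALLESCALDERA_TRAITS),
    )
    serrulatus_ovipara = SpeciesProfile(
        name="serrulatus_ovipara",
        measurements={
            "body_length": (2.00, 2.35),
            "hindfemur_width_mid": (0.050, 0.060),
            "marginal_seta_length": (0.030, 0.045),
            "spinal_seta_length": (0.020, 0.040),
        },
        integer_traits={"pseudosensoria_per_hindtibia": (31, 40)},
        categorical={
            "antennal_segments": 5,
            "dorsal_seta_shapes": ("dentate", "scale_like"),
            "dorsum_sculpture": "rugose",
            "ant3_seta_count": 2,
            "dorsal_setae_in_rows": True,
            "marginal_seta_shape": "dentate",
            "empodial_setae": "spatulate",
            "tergite8_covers_cauda": True,
            "cauda_shape": "rounded",
        },
    )
    # An outgroup-conforming chaitophorine: six-segmented antenna, long
    # acuminate setae, tubular siphunculus on segment VI, knobbed cauda.
    outgroup_apterous = SpeciesProfile(
        name="outgroup_apterous",
        measurements={
            "body_length": (1.80, 2.10),
            "body_width_at_siphunculi": (0.75, 0.85),
            "antenna_length": (0.80, 0.95),
            "ant3_apical_seta_length": (0.030, 0.040),
            "ant3_width_mid": (0.020, 0.022),
            "processus_terminalis_length": (0.070, 0.075),
            "terminal_segment_base_length": (0.080, 0.085),
            "hindfemur_length": (0.450, 0.480),
            "midfemur_length": (0.330, 0.350),
        },
        categorical={
            "antennal_segments": 6,
            "dorsal_seta_shapes": ("acuminate",),
            "cuticle_denticulate": False,
            "dorsal_wrinkles": False,
            "siphunculus_segment": 6,
            "siphunculus_orifice": "tube",
            "tergite8_covers_cauda": False,
            "cauda_shape": "knobbed",
        },
    )
    return {
        p.name: p
        for p in (
            vallescaldera_apterous,
            vallescaldera_ovipara,
            serrulatus_ovipara,
            outgroup_apterous,
        )
    }


def builtin_profile(name: str) -> SpeciesProfile:
    profiles = builtin_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise MorphocladError(
            f"unknown profile {name!r}; available: {sorted(profiles)}"
        ) from None
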