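"""Per-character fit and ensemble consistency / retention indices.

For a binary character on a tree, the observed steps s come from Fitch
optimisation, the minimum conceivable steps m is 1 when both states occur
(else 0), and the maximum conceivable steps g is the length on the
star-equivalent worst tree, i.e. the smaller of the two state counts.
Over all characters: CI = 100 M/S and RI = 100 (G-S)/(G-M), both reported
truncated to integer percent (and as exact rationals for programmatic
use).  All characters, informative or not, enter the sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .datamodel import MISSING, CharacterMatrix, MorphocladError, PhyloTree
from .parsimony import per_character_steps


def min_steps(column: Sequence[int]) -> int:
    """Minimum conceivable changes of a binary column on any tree:
    1 when both states are present, otherwise 0."""
    col = np.asarray(column)
    return int((col == 0).any() and (col == 1).any())


def max_steps(column: Sequence[int]) -> int:
    """Maximum changes a binary column can need on any tree (the length on
    a star tree): the smaller of the two state counts."""
    col = np.asarray(column)
    return int(min(int((col == 0).sum()), int((col == 1).sum())))


@dataclass(frozen=True)
class FitSummary:
    """Per-character and ensemble parsimony fit of a tree to a matrix."""

    observed: tuple[int, ...]   # s_i, Fitch steps per character
    minimum: tuple[int, ...]    # m_i
    maximum: tuple[int, ...]    # g_i
    length: int                 # S
    min_total: int              # M
    max_total: int              # G
    ci: Optional[int]           # floor(100 M / S), None when S = 0
    ri: Optional[int]           # floor(100 (G-S)/(G-M)), None when G = M
    ci_exact: Optional[Fraction]
    ri_exact: Optional[Fraction]


def ensemble_indices(matrix: CharacterMatrix, tree: PhyloTree) -> FitSummary:
    """Score a tree against a matrix and report CI and RI.

    Indices are truncated (floored) on the percent scale; the exact
    rationals are exposed alongside.  RI is undefined (None) when every
    character is uninformative (G = M); CI is undefined on an invariant
    matrix (S = 0).
    """
    observed = per_character_steps(tree, matrix)
    minimum = np.array([min_steps(matrix.column(j)) for j in range(matrix.nchar)])
    maximum = np.array([max_steps(matrix.column(j)) for j in range(matrix.nchar)])
    if (observed < minimum).any() or (observed > maximum).any():
        raise MorphocladError("per-character steps outside [min, max] bounds")
    S, M, G = int(observed.sum()), int(minimum.sum()), int(maximum.sum())
    ci_exact = Fraction(M, S) if S > 0 else None
    ri_exact = Fraction(G - S, G - M) if G > M else None
    return FitSummary(
        observed=tuple(int(x) for x in observed),
        minimum=tuple(int(x) for x in minimum),
        maximum=tuple(int(x) for x in maximum),
        length=S,
        min_total=M,
        max_total=G,
        ci=(100 * M) // S if S > 0 else None,
        ri=(100 * (G - S)) // (G - M) if G > M else None,
        ci_exact=ci_exact,
        ri_exact=ri_exact,
    )


def fit_table(summary: FitSummary) -> str:
    """Tabular (TSV) rendering: one row per character plus an ensemble row."""
    lines = ["character\tobserved\tminimum\tmaximum"]
    for j, (s, m, g) in enumerate(
        zip(summary.observed, summary.minimum, summary.maximum)
    ):
        lines.append(f"{j}\t{s}\t{m}\t{g}")
    ci = "NA" if summary.ci is None else str(summary.ci)
    ri = "NA" if summary.ri is None else str(summary.ri)
    lines.append(
        f"ensemble\t{summary.length}\t{summary.min_total}\t{summary.max_total}"
    )
    lines.append(f"indices\tCI={ci}\tRI={ri}\t")
    return "\n".join(lines) + "\n"
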