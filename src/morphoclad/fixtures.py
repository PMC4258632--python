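"""Built-in study data: the Siphini character matrix and the COI barcode.

The matrix codes ten chaitophorine aphid taxa (nine Siphini plus the
outgroup *Chaitophorus leucomelas*, type species of Chaitophorinae) for
twelve equally weighted, unordered binary morphological characters.  The
barcode is the 652-nt COI fragment of *Atheroides vallescaldera*
(GenBank KJ737374).
"""

from __future__ import annotations

from importlib import resources

from .datamodel import BarcodeRecord, CharacterMatrix, CharacterMeta, Taxon
from .io import read_barcode_fasta

OUTGROUP = "Chaitophorus_leucomelas"

CHARACTER_DESCRIPTIONS = (
    "body length / body width at siphunculi (elongation)",
    "antennal segment number (six vs five)",
    "dorsal apical seta of antennal III / segment width at middle",
    "processus terminalis / base of terminal antennal segment",
    "hindfemur length / midfemur length",
    "dorsal seta shape (acuminate vs scale-like/denticulate/flabellate)",
    "denticulate or spiculate cuticle over most of body",
    "dorsal cuticular wrinkles and folds",
    "siphunculus base on abdominal segment VI vs V",
    "siphunculus orifice elevated on a tube vs flush/mound",
    "tergite VIII expanded posteriorly, hiding the cauda",
    "cauda constricted into an apical knob vs broadly rounded",
)

# taxon label, role, states for characters 0..11
_MATRIX_ROWS = (
    ("Chaitophorus_leucomelas", "outgroup", "000000000000"),
    ("Sipha_elegans",           "ingroup",  "010000101101"),
    ("Sipha_maydis",            "ingroup",  "010000101101"),
    ("Sipha_flava",             "ingroup",  "010000101100"),
    ("Sipha_glyceriae",         "ingroup",  "010000001100"),
    ("Caricosipha_paniculatae", "ingroup",  "010000000000"),
    ("Laingia_psammae",         "ingroup",  "110000000111"),
    ("Chaetosiphella_berlesei", "ingroup",  "010100101101"),
    ("Atheroides_vallescaldera","ingroup",  "111011111111"),
    ("Atheroides_serrulatus",   "ingroup",  "111011111111"),
)


def load_siphini_matrix() -> CharacterMatrix:
    """The published 10-taxon x 12-character Siphini matrix.

    Taxon and character order follow the printed table; the matrix has
    no missing or inapplicable cells and all weights are equal.
    """
    taxa = [Taxon(name, role) for name, role, _ in _MATRIX_ROWS]
    states = [[int(s) for s in row] for _, _, row in _MATRIX_ROWS]
    characters = [
        CharacterMeta(j, CHARACTER_DESCRIPTIONS[j]) for j in range(12)
    ]
    return CharacterMatrix(taxa, states, characters)


def load_coi_barcode() -> BarcodeRecord:
    """The 652-nt COI barcode of *A. vallescaldera* (GenBank KJ737374)."""
    text = (
        resources.files("morphoclad")
        .joinpath("data/coi_kj737374.fasta")
        .read_text()
    )
    return read_barcode_fasta(text)


#: Newick for the single 14-step tree hypothesis after collapsing the
#: unsupported Sipha (Rungsia) / Chaetosiphella nodes: those three taxa
#: fall into a polytomy together with the Laingia + Atheroides clade.
#: Confirmed against this package's own exhaustive search in the tests
#: (it equals both the strict consensus of all binary optima and the
#: zero-length-branch collapse of any one of them).
REFERENCE_TOPOLOGY_NEWICK = (
    "(Chaitophorus_leucomelas,(Caricosipha_paniculatae,(Sipha_glyceriae,"
    "(Sipha_flava,(Sipha_elegans,Sipha_maydis,Chaetosiphella_berlesei,"
    "(Laingia_psammae,(Atheroides_vallescaldera,Atheroides_serrulatus))))"
    ")));"
)
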