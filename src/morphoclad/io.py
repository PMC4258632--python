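"""Readers and writers for character matrices, trees and barcode records.

Supported matrix dialects:

* ``nexus`` — a minimal ``DATA`` block with ``FORMAT SYMBOLS="01" MISSING=?``
  (parsed through :mod:`dendropy`);
* ``tnt`` — the ``xread`` dialect;
* ``csv`` — taxa as rows, characters as columns (through :mod:`pandas`).

Newick parsing goes through dendropy and supports multifurcations; writing
emits a canonical newick string with underscored labels.
"""

from __future__ import annotations

import io as _io
from typing import TextIO, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    MISSING,
    BarcodeRecord,
    CharacterMatrix,
    CharacterMeta,
    MatrixFormatError,
    Node,
    PhyloTree,
    Taxon,
    TreeFormatError,
    canonical_label,
)

MATRIX_DIALECTS = ("nexus", "tnt", "csv")

_STATE_TO_SYMBOL = {0: "0", 1: "1", MISSING: "?"}
_SYMBOL_TO_STATE = {"0": 0, "1": 1, "?": MISSING, "-": MISSING}


def _as_text(source: Union[str, TextIO]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return source


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------


def read_matrix(source: Union[str, TextIO], dialect: str) -> CharacterMatrix:
    """Parse a character matrix from text in the named dialect."""
    text = _as_text(source)
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    if dialect == "csv":
        return _read_csv(text)
    raise MatrixFormatError(
        f"unknown dialect {dialect!r}; expected one of {MATRIX_DIALECTS}"
    )


def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Serialise a matrix to text in the named dialect."""
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    if dialect == "csv":
        return _write_csv(matrix)
    raise MatrixFormatError(
        f"unknown dialect {dialect!r}; expected one of {MATRIX_DIALECTS}"
    )


def _rows_to_matrix(rows: list[tuple[str, str]], where: str) -> CharacterMatrix:
    if not rows:
        raise MatrixFormatError(f"no taxon rows found in {where} input")
    width = len(rows[0][1])
    states = []
    for name, symbols in rows:
        if len(symbols) != width:
            raise MatrixFormatError(
                f"ragged grid: taxon {name!r} has {len(symbols)} states, "
                f"expected {width}"
            )
        try:
            states.append([_SYMBOL_TO_STATE[s] for s in symbols])
        except KeyError as exc:
            raise MatrixFormatError(
                f"taxon {name!r}: unknown state symbol {exc.args[0]!r}"
            ) from exc
    return CharacterMatrix([Taxon(n) for n, _ in rows], states)


def _read_nexus(text: str) -> CharacterMatrix:
    try:
        cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise MatrixFormatError(f"NEXUS parse error: {exc}") from exc
    rows = []
    for taxon in cm.taxon_namespace:
        symbols = "".join(str(s.symbol) for s in cm[taxon])
        rows.append((canonical_label(taxon.label), symbols))
    return _rows_to_matrix(rows, "NEXUS")


def _write_nexus(matrix: CharacterMatrix) -> str:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    MATRIX",
    ]
    width = max(len(t.label) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.states):
        symbols = "".join(_STATE_TO_SYMBOL[int(s)] for s in row)
        lines.append(f"        {taxon.label:<{width}}{symbols}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def _read_tnt(text: str) -> CharacterMatrix:
    body = text
    idx = body.lower().find("xread")
    if idx < 0:
        raise MatrixFormatError("TNT input has no 'xread' statement")
    body = body[idx + len("xread"):]
    end = body.find(";")
    if end < 0:
        raise MatrixFormatError("TNT xread block not terminated by ';'")
    body = body[:end]
    # optional quoted title
    s = body.lstrip()
    if s.startswith("'"):
        close = s.find("'", 1)
        if close < 0:
            raise MatrixFormatError("unterminated TNT title quote")
        s = s[close + 1:]
    tokens = s.split()
    if len(tokens) < 2:
        raise MatrixFormatError("TNT xread needs NCHAR and NTAX counts")
    try:
        nchar, ntax = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise MatrixFormatError(
            f"TNT dimension tokens not integers: {tokens[:2]}"
        ) from exc
    cells = tokens[2:]
    if len(cells) != 2 * ntax:
        raise MatrixFormatError(
            f"TNT xread expected {ntax} name/row pairs, got "
            f"{len(cells)} tokens"
        )
    rows = []
    seen = set()
    for i in range(ntax):
        name, symbols = cells[2 * i], cells[2 * i + 1]
        if name in seen:
            raise MatrixFormatError(f"duplicate taxon {name!r} in TNT input")
        seen.add(name)
        if len(symbols) != nchar:
            raise MatrixFormatError(
                f"taxon {name!r}: row has {len(symbols)} states, "
                f"header says NCHAR={nchar}"
            )
        rows.append((canonical_label(name), symbols))
    return _rows_to_matrix(rows, "TNT")


def _write_tnt(matrix: CharacterMatrix) -> str:
    lines = ["xread", f"{matrix.nchar} {matrix.ntax}"]
    width = max(len(t.label) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.states):
        symbols = "".join(_STATE_TO_SYMBOL[int(s)] for s in row)
        lines.append(f"{taxon.label:<{width}}{symbols}")
    lines += [";", ""]
    return "\n".join(lines)


def _read_csv(text: str) -> CharacterMatrix:
    try:
        frame = pd.read_csv(_io.StringIO(text), index_col=0, dtype=str)
    except Exception as exc:
        raise MatrixFormatError(f"CSV parse error: {exc}") from exc
    if frame.isna().any().any():
        raise MatrixFormatError("CSV grid has empty cells; use '?' for missing")
    rows = [
        (canonical_label(name), "".join(frame.loc[name]))
        for name in frame.index
    ]
    return _rows_to_matrix(rows, "CSV")


def _write_csv(matrix: CharacterMatrix) -> str:
    frame = pd.DataFrame(
        [
            [_STATE_TO_SYMBOL[int(s)] for s in row]
            for row in matrix.states
        ],
        index=[t.label for t in matrix.taxa],
        columns=[str(c.index) for c in matrix.characters],
    )
    frame.index.name = "taxon"
    return frame.to_csv()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string (multifurcations allowed) into a PhyloTree."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeFormatError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        children = dnode.child_nodes()
        if not children:
            if dnode.taxon is None:
                raise TreeFormatError("newick leaf without a label")
            return Node(canonical_label(dnode.taxon.label))
        return Node(None, [convert(c) for c in children])

    tree = PhyloTree(convert(dtree.seed_node), rooted=False)
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise TreeFormatError("duplicate leaf labels in newick input")
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Emit a newick string; leaf labels are underscore-canonicalised."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return canonical_label(node.label)
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(tree.root) + ";"


def read_trees_newick(source: Union[str, TextIO]) -> list[PhyloTree]:
    """Read one tree per non-empty newick statement."""
    text = _as_text(source)
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";"))
    return trees


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------


def read_barcode_fasta(source: Union[str, TextIO]) -> BarcodeRecord:
    """Read the first record of a FASTA stream as a barcode."""
    handle = _io.StringIO(_as_text(source))
    for record in SeqIO.parse(handle, "fasta"):
        return BarcodeRecord(record.id, str(record.seq))
    raise MatrixFormatError("FASTA input contains no records")


def write_barcode_fasta(record: BarcodeRecord) -> str:
    lines = [f">{record.identifier}"]
    seq = record.sequence
    lines += [seq[i:i + 70] for i in range(0, len(seq), 70)]
    return "\n".join(lines) + "\n"
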