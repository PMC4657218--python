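"""Readers and writers for the file formats the toolkit touches.

Formats supported: FASTA and relaxed sequential PHYLIP for alignments
(via Biopython), Newick with optional internal-node support labels for
trees (via DendroPy), and RAxML-style partition tables.  NEXUS and
interleaved PHYLIP are out of scope.

Conventions
-----------
* Residues are uppercased on read; ``-``, ``?`` and ``X`` all count as
  non-data (missing) states, for interoperability with trimAl/RAxML.
* Partition coordinates are 1-based inclusive, the RAxML convention.
* Taxon labels containing whitespace are sanitized to underscores on
  write; a collision after sanitization is an error.
* Newick internal-node labels are interpreted as support values where
  numeric.  The support scale is detected per file: if every value in a
  file is <= 1 the values are taken as proportions and normalized to
  percent, so mixed RAxML (0-100) and PhyloBayes (0-1) inputs are
  comparable downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import dendropy
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MISSING_CHARS = frozenset("-?X")

__all__ = [
    "AMINO_ACIDS",
    "MISSING_CHARS",
    "Alignment",
    "PartitionEntry",
    "PartitionTable",
    "read_alignment",
    "write_alignment",
    "read_trees",
    "write_trees",
    "read_partition_table",
    "write_partition_table",
    "is_missing",
]


def is_missing(residue: str) -> bool:
    """True if a single character counts as a missing-data cell."""
    return residue.upper() in MISSING_CHARS


@dataclass
class Alignment:
    """An ordered taxon -> sequence map for one locus (or a supermatrix).

    Parameters
    ----------
    name
        Locus identifier.
    rows
        Ordered ``(taxon label, sequence)`` pairs.  All sequences must
        have identical length and labels must be unique.
    """

    name: str
    rows: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            ragged = sorted(
                {taxon for taxon, seq in self.rows if len(seq) != len(self.rows[0][1])}
            )
            raise ValueError(
                f"alignment {self.name!r}: ragged sequence lengths for taxa {ragged}"
            )
        labels = [taxon for taxon, _ in self.rows]
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValueError(f"alignment {self.name!r}: duplicate taxon labels {dupes}")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def taxa(self) -> List[str]:
        return [taxon for taxon, _ in self.rows]

    def sequence(self, taxon: str) -> str:
        for label, seq in self.rows:
            if label == taxon:
                return seq
        raise KeyError(taxon)


@dataclass(frozen=True)
class PartitionEntry:
    model: str
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(
                f"partition {self.name!r}: invalid range {self.start}-{self.end}"
            )


@dataclass
class PartitionTable:
    """Ordered locus coordinate ranges tiling a concatenated matrix.

    Ranges must be contiguous, non-overlapping and cover ``1..total``
    exactly (validated on construction).
    """

    entries: List[PartitionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected_start = 1
        for entry in self.entries:
            if entry.start != expected_start:
                raise ValueError(
                    f"partition {entry.name!r} starts at {entry.start}, "
                    f"expected {expected_start} (ranges must tile the matrix)"
                )
            expected_start = entry.end + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1].end if self.entries else 0


def _sanitize_label(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def _sanitized_rows(aln: Alignment) -> List[Tuple[str, str]]:
    rows = [(_sanitize_label(taxon), seq) for taxon, seq in aln.rows]
    labels = [t for t, _ in rows]
    if len(set(labels)) != len(labels):
        dupes = sorted({t for t in labels if labels.count(t) > 1})
        raise ValueError(f"taxon label collision after sanitization: {dupes}")
    return rows


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read one alignment from ``path``.

    ``format`` is ``"fasta"`` or ``"phylip-relaxed"`` (sequential).
    Taxon order is preserved and residues uppercased.  Raises
    ``ValueError`` on an empty file, ragged rows, or a malformed record.
    """
    path = Path(path)
    if format == "fasta":
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
        if not records:
            raise ValueError(f"{path}: no records")
        rows = [(rec.description or rec.id, str(rec.seq).upper()) for rec in records]
    elif format == "phylip-relaxed":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise ValueError(f"{path}: malformed relaxed PHYLIP: {exc}") from exc
        rows = [(rec.id, str(rec.seq).upper()) for rec in msa]
        if not rows:
            raise ValueError(f"{path}: no records")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return Alignment(name=path.stem, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write ``aln`` to ``path`` so that :func:`read_alignment` recovers it.

    The relaxed PHYLIP output is sequential, one taxon per line, with the
    standard ``"n_taxa n_cols"`` header.
    """
    path = Path(path)
    rows = _sanitized_rows(aln)
    if format == "fasta":
        with open(path, "w") as handle:
            for taxon, seq in rows:
                handle.write(f">{taxon}\n{seq}\n")
    elif format == "phylip-relaxed":
        with open(path, "w") as handle:
            handle.write(f"{len(rows)} {aln.length}\n")
            for taxon, seq in rows:
                handle.write(f"{taxon}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _annotate_supports(trees: Sequence[dendropy.Tree]) -> None:
    """Attach a ``support`` attribute (percent scale) to labelled internal nodes.

    Scale detection is per tree collection (one file): if every numeric
    internal label is <= 1 they are read as proportions and multiplied
    by 100.
    """
    values = []
    nodes = []
    for tree in trees:
        for node in tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            label = node.label
            if label is None:
                continue
            try:
                value = float(label)
            except ValueError:
                continue
            values.append(value)
            nodes.append(node)
    scale = 100.0 if values and max(values) <= 1.0 else 1.0
    for node, value in zip(nodes, values):
        node.support = value * scale


def read_trees(path: str | Path) -> List[dendropy.Tree]:
    """Read one or more Newick trees from a file.

    Edge lengths and internal-node support labels are parsed when
    present; supports are normalized to the percent scale and stored on
    each node as ``node.support`` (original labels are preserved for
    round-tripping).  Raises ``ValueError`` on malformed Newick.
    """
    path = Path(path)
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ValueError(f"{path}: failed to parse Newick: {exc}") from exc
    if len(trees) == 0:
        raise ValueError(f"{path}: no trees")
    result = list(trees)
    _annotate_supports(result)
    return result


def write_trees(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    """Write trees as one Newick string per line (supports as node labels)."""
    with open(path, "w") as handle:
        for tree in trees:
            newick = tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            handle.write(newick + "\n")


_PARTITION_LINE = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")


def write_partition_table(pt: PartitionTable, path: str | Path) -> None:
    """Write a RAxML-style partition file, one ``MODEL, name = start-end`` line per entry."""
    with open(path, "w") as handle:
        for entry in pt.entries:
            handle.write(f"{entry.model}, {entry.name} = {entry.start}-{entry.end}\n")


def read_partition_table(path: str | Path) -> PartitionTable:
    """Read a partition file written by :func:`write_partition_table`."""
    entries = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            match = _PARTITION_LINE.match(line)
            if match is None:
                raise ValueError(f"{path}:{lineno}: malformed partition line {line!r}")
            model, name, start, end = match.groups()
            entries.append(PartitionEntry(model, name, int(start), int(end)))
    return PartitionTable(entries)
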