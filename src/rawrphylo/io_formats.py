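"""Readers/writers for the formats the pipeline touches.

FASTA (aligned and unaligned), Newick trees with optional internal-node
support labels, and RAxML-style partition files. In-memory containers are
two thin dataclasses (:class:`SequenceSet`, :class:`Alignment`) plus
:class:`dendropy.Tree` for trees.

Alphabet policy: sequences are upper-cased on read; IUPAC ambiguity codes
(including N) are collapsed to ``N``; the only gap character is ``-``
(``.`` is rejected). Internally all coordinates are 0-based half-open;
partition files use RAxML's 1-based inclusive dialect and are converted at
the boundary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "Alignment",
    "PartitionScheme",
    "parse_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "parse_partition_file",
]

GAP = "-"
_AMBIGUITY = set("RYSWKMBDHVN")
_VALID = set("ACGTN") | {GAP}


class FormatError(ValueError):
    """Malformed input file or record."""


def _normalize(label: str, seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in "ACGT" or ch == GAP:
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
        else:
            raise FormatError(f"invalid character {ch!r} in sequence {label!r}")
    return "".join(out)


@dataclass(frozen=True)
class SequenceSet:
    """Unaligned, possibly unequal-length DNA sequences with unique labels."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate taxon labels")
        if any(not lab for lab in labels):
            raise FormatError("empty taxon label")
        for lab, seq in self.records:
            if GAP in seq:
                raise FormatError(f"gap character in unaligned sequence {lab!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Alignment:
    """Rectangular matrix of aligned characters over {A,C,G,T,N,-}."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate taxon labels")
        if self.records:
            ncol = len(self.records[0][1])
            for lab, row in self.records:
                if len(row) != ncol:
                    raise FormatError(
                        f"ragged alignment: row {lab!r} has length {len(row)}, "
                        f"expected {ncol}"
                    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.records)

    @property
    def rows(self) -> tuple[str, ...]:
        return tuple(row for _, row in self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered, disjoint 0-based half-open column intervals of a supermatrix."""

    partitions: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, start, end in self.partitions:
            if not (0 <= start < end):
                raise FormatError(f"empty or negative interval for partition {name!r}")
            for s, e in seen:
                if start < e and s < end:
                    raise FormatError(f"partition {name!r} overlaps a previous one")
            seen.append((start, end))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)


def parse_fasta(text: str, aligned: bool = False) -> SequenceSet | Alignment:
    """Parse FASTA text into a :class:`SequenceSet` or (if ``aligned``) an
    :class:`Alignment`.

    Lower-case input is folded to upper case; ambiguity codes map to ``N``.
    Duplicate labels and (under ``aligned``) ragged rows raise
    :class:`FormatError`.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append((rec.id, _normalize(rec.id, str(rec.seq))))
    if aligned:
        return Alignment(tuple(records))
    for lab, seq in records:
        if GAP in seq:
            raise FormatError(f"gap character in unaligned FASTA record {lab!r}")
    return SequenceSet(tuple(records))


def write_fasta(x: SequenceSet | Alignment, width: int = 70) -> str:
    """Serialize to multi-line FASTA; round-trips through :func:`parse_fasta`."""
    chunks = []
    for lab, seq in x.records:
        chunks.append(f">{lab}\n")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width] + "\n")
    return "".join(chunks)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick tree, keeping internal-node labels (support values).

    The tree is treated as unrooted for all downstream bipartition work.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"failed to parse Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, include_support: bool = True) -> str:
    """Serialize a tree to Newick. Internal-node labels (support values) are
    kept when ``include_support`` is set, stripped otherwise."""
    t = tree.clone(depth=1)
    if not include_support:
        for node in t.internal_nodes():
            node.label = None
    return t.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


_PARTITION_RE = re.compile(
    r"^\s*(?:DNA\s*,\s*)?(?P<name>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def parse_partition_file(text: str) -> PartitionScheme:
    """Parse RAxML-style ``DNA, name = start-end`` lines (1-based inclusive)
    into a 0-based half-open :class:`PartitionScheme`."""
    parts = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _PARTITION_RE.match(line)
        if m is None:
            raise FormatError(f"line {lineno}: cannot parse partition line {line!r}")
        start = int(m.group("start"))
        end = int(m.group("end"))
        if start < 1 or end < start:
            raise FormatError(f"line {lineno}: bad interval {start}-{end}")
        parts.append((m.group("name"), start - 1, end))
    return PartitionScheme(tuple(parts))
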