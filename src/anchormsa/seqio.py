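"""Reading and writing of multi-FASTA files and gapped alignments.

Sequences are kept as plain uppercase strings over the nucleotide alphabet
(with IUPAC ambiguity characters preserved but flagged); gapped alignments
use ``-`` as the only gap character.  All coordinates downstream are 0-based
half-open intervals, and the 0-based position of a record in its input file
is the sequence index used everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

GAP = "-"
NUCLEOTIDES = frozenset("ACGT")

__all__ = [
    "GAP",
    "NUCLEOTIDES",
    "FastaError",
    "SequenceRecord",
    "SequenceSet",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
]


class FastaError(ValueError):
    """Raised for malformed FASTA input or ill-formed alignments."""


def _normalize(residues: str, record_id: str) -> str:
    """Uppercase, map U->T, and reject whitespace/gap characters."""
    s = residues.upper().replace("U", "T")
    if any(c.isspace() for c in s):
        raise FastaError(f"record {record_id!r}: residues contain whitespace")
    if "-" in s or "." in s:
        raise FastaError(
            f"record {record_id!r}: gap characters ('-' or '.') are not "
            "allowed in unaligned input; degap the sequences first"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (id = FASTA header up to whitespace)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record with empty id")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        """True when any residue falls outside the A/C/G/T alphabet."""
        return any(c not in NUCLEOTIDES for c in set(self.residues))


@dataclass(frozen=True)
class SequenceSet:
    """Ordered collection of sequences; record order fixes sequence indices."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise FastaError("a SequenceSet needs at least one record")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def A(self) -> float:
        """Mean sequence length (total length L = A * N)."""
        return self.total_length / self.N

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return self.N

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        return SequenceSet(tuple(SequenceRecord(i, s) for i, s in pairs))


@dataclass(frozen=True)
class Alignment:
    """Gapped sequence matrix; degapping any row reproduces its input."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows):
            raise FastaError("alignment ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise FastaError("alignment rows have unequal lengths")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def N(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def check_roundtrip(self, seqs: SequenceSet) -> None:
        """Assert that degapping every row reproduces the input sequences."""
        if seqs.N != self.N:
            raise FastaError("alignment and sequence set differ in size")
        for i, rec in enumerate(seqs):
            if self.degapped(i) != rec.residues:
                raise FastaError(
                    f"row {i} ({self.ids[i]!r}) does not degap to its input "
                    "sequence"
                )


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-FASTA file into a :class:`SequenceSet`.

    Residues are uppercased and U is mapped to T.  Characters outside
    A/C/G/T are preserved (they are later excluded from k-tuple counting).
    Empty files, duplicate ids and zero-length records are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id  # header token up to first whitespace
        if rid in seen:
            raise FastaError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        residues = _normalize(str(rec.seq), rid)
        if not residues:
            raise FastaError(f"zero-length record {rid!r} in {path}")
        records.append(SequenceRecord(rid, residues))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return SequenceSet(tuple(records))


def _write_wrapped(handle, name: str, body: str, width: int = 60) -> None:
    handle.write(f">{name}\n")
    for i in range(0, len(body), width):
        handle.write(body[i : i + width] + "\n")
    if not body:
        handle.write("")  # empty body: header line only


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            _write_wrapped(fh, rec.id, rec.residues)


def write_alignment(
    aln: Alignment,
    path: str | Path,
    check_against: SequenceSet | None = None,
) -> None:
    """Write a gapped alignment as aligned multi-FASTA ('-' gaps, 60 cols).

    When *check_against* is given, the degap round-trip invariant is
    verified before anything is written.
    """
    if len({len(r) for r in aln.rows}) > 1:  # defensive; ctor also checks
        raise FastaError("refusing to write alignment with unequal row lengths")
    if check_against is not None:
        aln.check_roundtrip(check_against)
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            _write_wrapped(fh, name, row)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned multi-FASTA file ('-' gaps) into an Alignment."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        row = str(rec.seq).upper().replace("U", "T")
        if "." in row:
            raise FastaError(
                f"record {rec.id!r}: '.' gaps are not supported, use '-'"
            )
        ids.append(rec.id)
        rows.append(row)
    if not ids:
        raise FastaError(f"no FASTA records found in {path}")
    return Alignment(tuple(ids), tuple(rows))
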