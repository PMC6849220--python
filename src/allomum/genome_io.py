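"""Sequence input/output with strict validation.

All coordinates in this package are 0-based, half-open on the forward
strand.  Sequences are normalized on input to the alphabet {A,C,G,T,N}:
lowercase is uppercased, U becomes T, and any other IUPAC ambiguity code
collapses to N (with a logged warning).  N never participates in a match
downstream, so gap runs in real assemblies are handled gracefully rather
than rejected.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: canonical alphabet after normalization
ALPHABET = frozenset("ACGTN")

# characters accepted without the collapse-to-N warning
_RECOGNIZED = frozenset("ACGTUNacgtun")

_NORMALIZE = str.maketrans(
    "acgtunU" + "RYSWKMBDHVryswkmbdhv",
    "ACGTNTT" + "N" * 20,
)


class FormatError(ValueError):
    """A sequence file or record violates the expected format."""


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Normalize a nucleotide string to uppercase {A,C,G,T,N}.

    Raises :class:`FormatError` when more than half of the characters are
    not recognizable nucleotide codes (the record is then considered
    non-nucleotide content, e.g. protein or garbage).
    """
    if not raw:
        raise FormatError(f"record {record_id!r}: empty sequence")
    n_invalid = sum(1 for c in raw if c not in _RECOGNIZED)
    if n_invalid * 2 > len(raw):
        raise FormatError(
            f"record {record_id!r}: {n_invalid}/{len(raw)} characters are not "
            "nucleotide codes; refusing non-nucleotide-dominant content"
        )
    norm = raw.translate(_NORMALIZE)
    bad = set(norm) - ALPHABET
    if bad:
        # unrecognized leftovers (digits, '-', '*', ...) also collapse to N
        norm = norm.translate(str.maketrans({c: "N" for c in bad}))
    n_collapsed = sum(1 for a, b in zip(raw.upper().replace("U", "T"), norm) if a != b)
    if n_collapsed:
        log.warning(
            "record %r: %d ambiguity/unknown character(s) collapsed to N",
            record_id, n_collapsed,
        )
    return norm


@dataclass
class SequenceRecord:
    """One named sequence over {A,C,G,T,N} (already normalized)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        extra = set(self.seq) - ALPHABET
        if extra:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(extra)} outside "
                "{A,C,G,T,N}; normalize first"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Read:
    """A sequencing read; ``qual`` is an optional phred string of equal length."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """An ordered collection of named sequences with a total-length coordinate space."""

    def __init__(self, name: str, records: Iterable[SequenceRecord]):
        self.name = name
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise FormatError(f"genome {name!r}: no sequences")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"genome {name!r}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        return self._by_id[rec_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.name == other.name and self.records == other.records

    def __repr__(self) -> str:
        return (
            f"Genome({self.name!r}, {len(self.records)} record(s), "
            f"{self.total_length} bp)"
        )


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fasta(path: PathLike, name: Optional[str] = None) -> Genome:
    """Parse a (possibly gzipped) FASTA file into a :class:`Genome`.

    ``name`` defaults to the file stem.  Multi-line and single-line dialects
    and CRLF line endings are accepted.  Duplicate ids, empty files and
    non-nucleotide content raise :class:`FormatError`.
    """
    path = Path(path)
    if name is None:
        name = path.name.removesuffix(".gz")
        name = name.rsplit(".", 1)[0] if "." in name else name
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id), desc)
            )
    if not records:
        raise FormatError(f"{path}: no sequences")
    return Genome(name, records)


def write_fasta(genome: Genome, path: PathLike, line_width: int = 60) -> None:
    """Write ``genome`` as FASTA with sequence lines wrapped at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with _open_text(path, "wt") as fh:
        for rec in genome:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i:i + line_width] + "\n")


def parse_reads(path: PathLike) -> Iterator[Read]:
    """Stream reads from a FASTQ or FASTA file (auto-detected by first character).

    FASTA input yields reads with ``qual=None``.  A FASTQ record whose
    quality length differs from its sequence length raises
    :class:`FormatError` naming the record.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
    if not first:
        raise FormatError(f"{path}: no sequences")
    if first == "@":
        fmt = "fastq"
    elif first == ">":
        fmt = "fasta"
    else:
        raise FormatError(f"{path}: neither FASTA ('>') nor FASTQ ('@') input")

    def _gen() -> Iterator[Read]:
        with _open_text(path) as fh:
            try:
                for rec in SeqIO.parse(fh, fmt):
                    seq = normalize_sequence(str(rec.seq), rec.id)
                    qual = None
                    if fmt == "fastq":
                        phred = rec.letter_annotations["phred_quality"]
                        qual = "".join(chr(q + 33) for q in phred)
                    yield Read(rec.id, seq, qual)
            except ValueError as exc:  # biopython reports malformed records this way
                raise FormatError(f"{path}: {exc}") from exc

    return _gen()


def write_reads(reads: Iterable[Read], path: PathLike, default_qual: str = "I") -> None:
    """Write reads as FASTQ; reads lacking qualities get a constant phred string."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else default_qual * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
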