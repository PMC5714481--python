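"""FASTA/FASTQ readers plus the deduplicated FASTA+/FASTQ+ dialects.

A FASTA+ (``.fasP``) or FASTQ+ record is an ordinary FASTA/FASTQ record whose
identifier ends in ``_<copy_number>`` (the ``SeqID_CopyNumber`` convention,
e.g. ``UniqueSeqX_1606515``): one entry stands for that many byte-identical
reads.  FASTQ+ stores the per-site mean Phred quality of all copies, rounded
half-up for the ASCII encoding.

Plain FASTA/FASTQ parsing is delegated to Biopython; only the ``+`` dialect
logic lives here.  Quality encoding is fixed at Phred+33.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
PHRED_MAX = 93  # '~' is the last printable Phred+33 character


class ParseError(ValueError):
    """A malformed FASTA/FASTQ/FASTA+ record; the message names the record."""


@dataclass(frozen=True)
class Read:
    """One sequencing read: id, bases and (for FASTQ input) Phred qualities."""

    read_id: str
    bases: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.quality is not None:
            if len(self.quality) != len(self.bases):
                raise ParseError(
                    f"read {self.read_id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            for q in self.quality:
                if not 0 <= q <= PHRED_MAX:
                    raise ParseError(
                        f"read {self.read_id!r}: Phred score {q} outside [0, {PHRED_MAX}]"
                    )


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed sequence: the FASTA+/FASTQ+ record.

    ``mean_quality`` holds the unrounded per-site mean Phred scores over all
    ``copy_number`` original copies; rounding happens only at encode time.
    """

    seq_id: str
    copy_number: int
    bases: str
    mean_quality: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")
        if self.mean_quality is not None and len(self.mean_quality) != len(self.bases):
            raise ValueError(
                f"record {self.seq_id!r}: mean_quality length != sequence length"
            )

    @property
    def header(self) -> str:
        return format_plus_id(self.seq_id, self.copy_number)


def format_plus_id(seq_id: str, copy_number: int) -> str:
    """Render the ``SeqID_CopyNumber`` header text."""
    return f"{seq_id}_{copy_number}"


def parse_plus_id(header: str) -> tuple[str, int]:
    """Split a ``SeqID_CopyNumber`` header on its LAST underscore.

    >>> parse_plus_id("UniqueSeqX_1606515")
    ('UniqueSeqX', 1606515)
    >>> parse_plus_id("a_b_3")
    ('a_b', 3)
    """
    base, sep, tail = header.rpartition("_")
    if not sep or not tail.isdigit() or int(tail) < 1:
        raise ParseError(
            f"header {header!r} is not in SeqID_CopyNumber form "
            "(no trailing positive integer after the final underscore)"
        )
    return base, int(tail)


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    """Open a path as text, transparently decompressing .gz; pass streams through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(path, "rb"))
        return open(path, "rt")
    return source


def read_fastq(source: str | Path | IO[str]) -> Iterator[Read]:
    """Yield Reads from 4-line FASTQ (Phred+33), in file order.

    Raises ParseError naming the record index on malformed input, including
    base/quality length mismatches and scores outside the printable Phred+33
    range (which also rejects Phred+64-encoded files by construction when
    scores decode above 93 — in practice Phred+64 is caught by the caller
    noticing implausible scores; characters below '!' fail here).
    """
    handle = _open_text(source)
    try:
        for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(handle), start=1):
            if len(seq) != len(qual):
                raise ParseError(
                    f"FASTQ record #{idx} ({title.split()[0] if title else '?'}): "
                    f"sequence length {len(seq)} != quality length {len(qual)}"
                )
            scores = tuple(ord(c) - PHRED_OFFSET for c in qual)
            for q in scores:
                if q < 0 or q > PHRED_MAX:
                    raise ParseError(
                        f"FASTQ record #{idx}: quality character outside the "
                        "printable Phred+33 range (is this file Phred+64?)"
                    )
            yield Read(title.split()[0], seq.upper(), scores)
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"malformed FASTQ stream: {exc}") from exc
    finally:
        if not isinstance(source, io.IOBase) and hasattr(handle, "close"):
            handle.close()


def read_fasta(source: str | Path | IO[str]) -> Iterator[Read]:
    """Yield quality-less Reads from FASTA (multi-line sequences allowed)."""
    handle = _open_text(source)
    try:
        first = handle.read(1)
        if first and first not in ">;":
            raise ParseError("FASTA stream: sequence data before the first '>' header")
        rest = handle.read()
        for title, seq in SimpleFastaParser(io.StringIO(first + rest)):
            if not seq:
                warnings.warn(f"FASTA record {title!r} has an empty sequence")
            yield Read(title.split()[0] if title else "", seq.upper(), None)
    finally:
        if not isinstance(source, io.IOBase) and hasattr(handle, "close"):
            handle.close()


def _encode_quality(means: Sequence[float]) -> str:
    # round half up, as 0.5 means come from averaging two integer scores
    chars = []
    for m in means:
        q = int(m + 0.5)
        q = min(max(q, 0), PHRED_MAX)
        chars.append(chr(q + PHRED_OFFSET))
    return "".join(chars)


def sort_unique(records: Iterable[UniqueRead]) -> list[UniqueRead]:
    """Deterministic FASTA+ emission order: copy number descending, then bases."""
    return sorted(records, key=lambda r: (-r.copy_number, r.bases))


def write_plus(
    records: Iterable[UniqueRead],
    out: IO[str] | str | Path,
    with_quality: bool = False,
) -> None:
    """Write FASTA+ (``>SeqID_Count``) or, with qualities, FASTQ+ records.

    Records are emitted in descending copy number, ties broken by the
    lexicographic order of the bases, so identical input multisets produce
    byte-identical files.
    """
    handle: IO[str]
    own = False
    if isinstance(out, (str, Path)):
        path = Path(out)
        handle = (
            io.TextIOWrapper(gzip.open(path, "wb"))
            if path.suffix == ".gz"
            else open(path, "wt")
        )
        own = True
    else:
        handle = out
    try:
        for rec in sort_unique(records):
            if with_quality:
                if rec.mean_quality is None:
                    raise ValueError(
                        f"record {rec.seq_id!r} lacks mean_quality; "
                        "cannot write FASTQ+"
                    )
                handle.write(
                    f"@{rec.header}\n{rec.bases}\n+\n{_encode_quality(rec.mean_quality)}\n"
                )
            else:
                handle.write(f">{rec.header}\n{rec.bases}\n")
    finally:
        if own:
            handle.close()


def read_plus(source: str | Path | IO[str]) -> Iterator[UniqueRead]:
    """Parse a FASTA+ or FASTQ+ file back into UniqueReads.

    The dialect is auto-detected from the first character ('@' = FASTQ+).
    """
    handle = _open_text(source)
    try:
        first = handle.read(1)
        stream = io.StringIO(first + handle.read())
        if first == "@":
            for title, seq, qual in FastqGeneralIterator(stream):
                seq_id, n = parse_plus_id(title.split()[0])
                means = tuple(float(ord(c) - PHRED_OFFSET) for c in qual)
                yield UniqueRead(seq_id, n, seq.upper(), means)
        elif first == ">":
            for title, seq in SimpleFastaParser(stream):
                seq_id, n = parse_plus_id(title.split()[0])
                yield UniqueRead(seq_id, n, seq.upper(), None)
        elif first:
            raise ParseError("not a FASTA+/FASTQ+ stream")
    finally:
        if not isinstance(source, io.IOBase) and hasattr(handle, "close"):
            handle.close()


def expand_plus(records: Iterable[UniqueRead]) -> Iterator[Read]:
    """Expand each UniqueRead into ``copy_number`` Reads (ids ``seq_id/k``).

    The inverse of collapsing, up to the documented lossy fields: the original
    read ids and the per-read quality vectors are gone; only the sequence
    multiset (and the mean quality) survives the roundtrip.
    """
    for rec in records:
        qual = (
            tuple(int(m + 0.5) for m in rec.mean_quality)
            if rec.mean_quality is not None
            else None
        )
        for k in range(1, rec.copy_number + 1):
            yield Read(f"{rec.seq_id}/{k}", rec.bases, qual)
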