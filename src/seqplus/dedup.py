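"""Collapse a read stream into unique sequences with copy numbers.

Deduplication is exact-match on the full upper-cased base string: two reads
collapse together iff their sequences are byte-identical (a prefix is never
merged with a longer read).  Per-site qualities of the copies are averaged
arithmetically; the whole mapping is lossless for sequence content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from seqplus.seqformats import Read, UniqueRead, sort_unique


@dataclass(frozen=True)
class DedupSummary:
    """Bookkeeping for one collapse run.

    ``size_ratio`` compares the plain-text bytes of the collapsed records
    against the original records (headers included); it is the statistic that
    tracks how redundancy — and hence read quality — drives compression.
    """

    n_reads: int
    n_unique: int
    max_copy: int
    size_ratio: float

    def __post_init__(self) -> None:
        assert self.n_unique <= self.n_reads
        assert self.max_copy <= self.n_reads


def average_quality(vectors: Sequence[Sequence[float]]) -> tuple[float, ...]:
    """Element-wise arithmetic mean of equal-length Phred vectors.

    For two copies this is (Q_1i + Q_2i)/2 at every site i; in general the
    flat mean over all original copies.
    """
    if not vectors:
        raise ValueError("average_quality needs at least one vector")
    length = len(vectors[0])
    for v in vectors:
        if len(v) != length:
            raise ValueError(
                f"quality length mismatch: expected {length}, got {len(v)}"
            )
    arr = np.asarray(vectors, dtype=float)
    return tuple(arr.mean(axis=0))


def quality_correlation(vectors: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise Pearson correlation matrix of quality vectors.

    Entries involving a zero-variance vector are undefined and reported as
    NaN.  Quality vectors of identical reads in real data correlate strongly,
    which is what justifies storing only their mean.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two quality vectors")
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("quality vectors must all have the same length")
    var = arr.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.asarray(corr, dtype=float)
    corr[var == 0.0, :] = np.nan
    corr[:, var == 0.0] = np.nan
    np.fill_diagonal(corr, np.where(var == 0.0, np.nan, 1.0))
    return corr


def _text_bytes_reads(reads: list[Read], with_quality: bool) -> int:
    total = 0
    for r in reads:
        if with_quality:
            # @id\nSEQ\n+\nQUAL\n
            total += 1 + len(r.read_id) + 1 + len(r.bases) + 1 + 2 + len(r.bases) + 1
        else:
            total += 1 + len(r.read_id) + 1 + len(r.bases) + 1
    return total


def _text_bytes_unique(records: list[UniqueRead], with_quality: bool) -> int:
    total = 0
    for u in records:
        header = len(u.seq_id) + 1 + len(str(u.copy_number))
        if with_quality:
            total += 1 + header + 1 + len(u.bases) + 1 + 2 + len(u.bases) + 1
        else:
            total += 1 + header + 1 + len(u.bases) + 1
    return total


def collapse(reads: Iterable[Read]) -> tuple[list[UniqueRead], DedupSummary]:
    """Collapse reads into one UniqueRead per distinct sequence.

    Copy number is the multiplicity of the sequence; mean_quality is the
    per-site mean over all copies when the input carries qualities.  Either
    every read has a quality vector or none does — a mixture cannot be
    averaged and raises ValueError.

    Unique records are assigned ids ``S1, S2, ...`` in the deterministic
    output order (copy number descending, ties by sequence), so the same
    input multiset always collapses to byte-identical output.
    """
    reads = list(reads)
    has_quality: bool | None = None
    counts: dict[str, int] = {}
    qual_sums: dict[str, np.ndarray] = {}
    for r in reads:
        if has_quality is None:
            has_quality = r.quality is not None
        elif (r.quality is not None) != has_quality:
            raise ValueError(
                "mixed presence/absence of quality scores across reads; "
                "cannot average qualities"
            )
        seq = r.bases.upper()
        counts[seq] = counts.get(seq, 0) + 1
        if has_quality:
            q = np.asarray(r.quality, dtype=float)
            if seq in qual_sums:
                if len(q) != len(qual_sums[seq]):
                    raise ValueError(
                        f"identical sequences with different quality lengths: {seq!r}"
                    )
                qual_sums[seq] += q
            else:
                qual_sums[seq] = q.copy()

    has_quality = bool(has_quality)
    provisional = [
        UniqueRead(
            "x",
            n,
            seq,
            tuple(qual_sums[seq] / n) if has_quality else None,
        )
        for seq, n in counts.items()
    ]
    uniques = [
        UniqueRead(f"S{rank}", u.copy_number, u.bases, u.mean_quality)
        for rank, u in enumerate(sort_unique(provisional), start=1)
    ]

    n_reads = len(reads)
    if n_reads == 0:
        summary = DedupSummary(0, 0, 0, 1.0)
    else:
        orig = _text_bytes_reads(reads, has_quality)
        new = _text_bytes_unique(uniques, has_quality)
        summary = DedupSummary(
            n_reads=n_reads,
            n_unique=len(uniques),
            max_copy=max(u.copy_number for u in uniques),
            size_ratio=new / orig if orig else 1.0,
        )
    assert sum(u.copy_number for u in uniques) == n_reads
    return uniques, summary
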