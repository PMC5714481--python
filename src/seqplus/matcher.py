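"""Map unique reads to a reference gene set.

A self-contained k-mer seeded, ungapped matcher: every gene is indexed on
both strands, read k-mers seed candidate diagonals, and each diagonal is
scored by counting matching bases over the read/gene overlap.  The score is
that match count; a hit is kept when the read has at least ``min_in_gene``
bases inside the gene, so reads overhanging a gene end (the 36-nt 3'-end
case) still count toward it.  A read is a *unique match* when exactly one
gene attains the top score, and a *shared read* when two or more tie.

Externally produced BLAST-style tabular hits (outfmt 6) can be ingested
instead, with ties decided on exact (bitscore, e-value) equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from seqplus.seqformats import ParseError, UniqueRead, parse_plus_id

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_K = 15
DEFAULT_MIN_IN_GENE = 25


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A reference gene; ``gene_id`` may embed coordinates as ``locus|start_end``."""

    gene_id: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Hit:
    """One read-to-gene hit.

    ``score`` is the matching-base count for the internal matcher, or the bit
    score for tabular input; ``evalue`` is carried only for tabular input.
    """

    gene_id: str
    score: float
    strand: str = "+"
    aligned_span_in_gene: int = 0
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("hit score must be >= 0")
        if self.evalue is not None and self.evalue <= 0:
            raise ValueError("e-value must be > 0")


@dataclass
class MatchEntry:
    """Per unique-read classification: copy number plus the tied-best gene set."""

    read_id: str
    copy_number: int
    best_hits: list[Hit]

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(h.gene_id for h in self.best_hits)

    @property
    def is_unique(self) -> bool:
        return len(self.best_hits) == 1

    @property
    def is_unmapped(self) -> bool:
        return not self.best_hits


@dataclass
class MatchTable:
    """All classified reads of one run, ready for allocation."""

    entries: list[MatchEntry] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(e.copy_number for e in self.entries)

    @property
    def unmapped_reads(self) -> int:
        return sum(e.copy_number for e in self.entries if e.is_unmapped)

    def to_tsv(self, out: IO[str]) -> None:
        out.write("read_id\tcopy_number\tgenes\tscores\n")
        for e in self.entries:
            genes = ",".join(sorted(h.gene_id for h in e.best_hits)) or "-"
            scores = ",".join(
                f"{h.score:g}" for h in sorted(e.best_hits, key=lambda h: h.gene_id)
            ) or "-"
            out.write(f"{e.read_id}\t{e.copy_number}\t{genes}\t{scores}\n")


class KmerIndex:
    """Exact k-mer -> (gene, strand, offset) lookup over both strands."""

    def __init__(self, genes: Sequence[GeneRecord], k: int = DEFAULT_K):
        if not genes:
            raise ValueError("empty gene list")
        if not 8 <= k <= 32:
            raise ValueError(f"k must be in [8, 32], got {k}")
        self.k = k
        self.genes: dict[str, GeneRecord] = {}
        # seeds: kmer -> list of (gene_id, strand, offset on the strand sequence)
        self.seeds: dict[str, list[tuple[str, str, int]]] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id!r}")
            self.genes[gene.gene_id] = gene
            if gene.length < k:
                warnings.warn(
                    f"gene {gene.gene_id!r} is shorter than k={k}; "
                    "excluded from the index"
                )
                continue
            seq = gene.bases.upper()
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for off in range(len(s) - k + 1):
                    kmer = s[off : off + k]
                    self.seeds.setdefault(kmer, []).append((gene.gene_id, strand, off))

    def strand_seq(self, gene_id: str, strand: str) -> str:
        seq = self.genes[gene_id].bases.upper()
        return seq if strand == "+" else reverse_complement(seq)


def build_index(genes: Sequence[GeneRecord], k: int = DEFAULT_K) -> KmerIndex:
    return KmerIndex(genes, k)


def _score_diagonal(read: str, gene_seq: str, diag: int) -> tuple[float, int]:
    """Score an ungapped placement where read position j aligns gene position diag+j.

    Returns (matching bases, read bases falling inside the gene).
    """
    lo = max(0, -diag)
    hi = min(len(read), len(gene_seq) - diag)
    if hi <= lo:
        return 0.0, 0
    span = hi - lo
    score = sum(1 for j in range(lo, hi) if read[j] == gene_seq[diag + j])
    return float(score), span


def match_read(
    read: UniqueRead | str,
    index: KmerIndex,
    min_in_gene: int = DEFAULT_MIN_IN_GENE,
) -> list[Hit]:
    """Seed-and-extend a read against the index; returns at most one Hit per gene.

    Candidate (gene, strand, diagonal) placements come from exact k-mer seeds;
    each is scored ungapped over the full overlap, and the best placement per
    gene is kept when its in-gene span reaches ``min_in_gene``.
    """
    seq = (read.bases if isinstance(read, UniqueRead) else read).upper()
    k = index.k
    if len(seq) < k:
        return []
    diagonals: set[tuple[str, str, int]] = set()
    for j in range(len(seq) - k + 1):
        for gene_id, strand, off in index.seeds.get(seq[j : j + k], ()):
            diagonals.add((gene_id, strand, off - j))
    best: dict[str, Hit] = {}
    for gene_id, strand, diag in diagonals:
        gene_seq = index.strand_seq(gene_id, strand)
        score, span = _score_diagonal(seq, gene_seq, diag)
        if span < min_in_gene:
            continue
        prev = best.get(gene_id)
        if prev is None or score > prev.score:
            best[gene_id] = Hit(gene_id, score, strand, span)
    return sorted(best.values(), key=lambda h: (-h.score, h.gene_id))


def classify(hits: Sequence[Hit]) -> list[Hit]:
    """The subset of hits achieving the maximal score (exact tie required).

    When e-values are present (tabular input) a tie additionally requires
    exact e-value equality, mirroring "the same e-value and the same
    BitScore" rule for shared reads.
    """
    if not hits:
        return []
    top = max(h.score for h in hits)
    best = [h for h in hits if h.score == top]
    if len(best) > 1 and any(h.evalue is not None for h in best):
        ev = min(h.evalue for h in best if h.evalue is not None)
        best = [h for h in best if h.evalue == ev]
    return sorted(best, key=lambda h: h.gene_id)


def match_all(
    uniques: Iterable[UniqueRead],
    index: KmerIndex,
    min_in_gene: int = DEFAULT_MIN_IN_GENE,
) -> MatchTable:
    """Match and classify a whole collapsed read set."""
    table = MatchTable()
    for u in uniques:
        hits = match_read(u, index, min_in_gene)
        table.entries.append(MatchEntry(u.seq_id, u.copy_number, classify(hits)))
    return table


def load_tabular_hits(
    source: str | Path | IO[str],
    copy_lookup: Mapping[str, int] | None = None,
) -> MatchTable:
    """Build a MatchTable from 12-column BLAST-style tabular hits.

    Columns: query, subject, identity, length, mismatches, gaps, qstart,
    qend, sstart, send, evalue, bitscore.  Query ids are expected in
    ``SeqID_CopyNumber`` form; an id without a copy suffix is treated as copy
    1 with a warning (or looked up in ``copy_lookup`` when provided).  The
    best-hit set per query is chosen by maximal bit score with ties on exact
    (bitscore, e-value) equality.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "rt")
        close = True
    else:
        handle = source
    per_query: dict[str, list[Hit]] = {}
    copies: dict[str, int] = {}
    order: list[str] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"tabular hits line {lineno}: expected 12 columns, got {len(cols)}"
                )
            query, subject = cols[0], cols[1]
            try:
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ParseError(f"tabular hits line {lineno}: {exc}") from exc
            if query not in copies:
                order.append(query)
                if copy_lookup is not None and query in copy_lookup:
                    copies[query] = copy_lookup[query]
                else:
                    try:
                        _, n = parse_plus_id(query)
                        copies[query] = n
                    except ParseError:
                        warnings.warn(
                            f"query {query!r} has no copy-number suffix; assuming 1"
                        )
                        copies[query] = 1
            strand = "+" if send >= sstart else "-"
            span = abs(send - sstart) + 1
            evalue = max(evalue, 1e-180)  # reported-as-0 e-values
            hit = Hit(subject, bitscore, strand, span, evalue)
            hits = per_query.setdefault(query, [])
            # keep the best hit per (query, subject)
            for i, prev in enumerate(hits):
                if prev.gene_id == subject:
                    if hit.score > prev.score:
                        hits[i] = hit
                    break
            else:
                hits.append(hit)
    finally:
        if close:
            handle.close()
    table = MatchTable()
    for query in order:
        table.entries.append(
            MatchEntry(query, copies[query], classify(per_query[query]))
        )
    return table
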