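"""Synthetic paralog families and short-read sets with known ground truth.

The generator emulates the data regimes the tool is built for: paralogous
genes at a chosen per-site divergence (including identical paralogs, the
degenerate equal-split case, and a segmented three-gene topology with a
conserved middle segment), substitution-only sequencing errors, high- or
poor-quality Phred profiles, and PCR-style duplication in which each
distinct fragment recurs with Zipf-distributed multiplicity — the
redundancy the FASTA+ format exploits.

Every read's source gene is recorded, so allocation accuracy can be scored
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from seqplus.matcher import GeneRecord
from seqplus.seqformats import Read

BASES = np.array(list("ACGT"))

# multiplicities above this are clipped: Zipf exponents near 1 have no finite
# mean, so the cap keeps simulated files desk-scale while preserving the
# one-dominant-read-among-many regime
MAX_COPY = 5_000


@dataclass(frozen=True)
class FamilySpec:
    """One paralog family: member count, ancestor length, per-site divergence."""

    n_members: int
    length: int
    divergence: float

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions for one simulated read set.

    abundances
        Expected number of distinct sequenced fragments per gene (Poisson
        mean); duplication multiplies these into total reads.
    error_rate
        Per-base substitution probability applied to each fragment before
        replication, so copies of one fragment stay identical.
    duplication_skew
        Zipf exponent (> 1) for per-fragment copy multiplicity; None emits
        each fragment once.
    quality
        "high": flat Phred ~ 38; "poor": mean decaying from 35 toward 15
        along the read with larger spread.
    """

    seed: int
    abundances: Mapping[str, float]
    read_length: int = 50
    error_rate: float = 0.0
    duplication_skew: float | None = None
    quality: str = "high"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.duplication_skew is not None and self.duplication_skew <= 1:
            raise ValueError("duplication_skew must be > 1")
        if self.quality not in ("high", "poor"):
            raise ValueError("quality must be 'high' or 'poor'")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(BASES, size=length)


def _diverge(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to one of the 3 other bases."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def make_family(
    seed: int,
    n_members: int,
    length: int,
    divergence: float,
    segmented: bool = False,
    prefix: str = "G",
) -> list[GeneRecord]:
    """Simulate one paralog family from a random ancestor.

    Default mode derives each member by independent per-site substitution at
    the divergence rate (divergence 0 gives identical members).  Segmented
    mode builds the idealised three-gene topology of one conserved middle
    third shared by all members, a first third identical between the second
    and third members but diverged in the first, and a fully diverged last
    third — the structure that defeats naive one-shot allocation.
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, length)
    if not segmented:
        members = [_diverge(rng, ancestor, divergence) for _ in range(n_members)]
    else:
        if n_members != 3:
            raise ValueError("segmented mode builds exactly 3 members")
        third = length // 3
        rate = divergence if divergence > 0 else 0.3
        first_bc = _diverge(rng, ancestor[:third], rate)
        members = []
        for m in range(3):
            first = ancestor[:third] if m == 0 else first_bc
            middle = ancestor[third : 2 * third]
            last = _diverge(rng, ancestor[2 * third :], rate)
            members.append(np.concatenate([first, middle, last]))
    return [
        GeneRecord(f"{prefix}{chr(ord('A') + m)}", "".join(members[m]))
        for m in range(n_members)
    ]


def _qualities(
    rng: np.random.Generator, length: int, regime: str
) -> tuple[int, ...]:
    if regime == "high":
        q = rng.normal(38.0, 2.0, size=length)
    else:
        decay = np.linspace(35.0, 15.0, num=length)
        q = rng.normal(decay, 6.0)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 40))


def simulate_reads(
    config: SimConfig, genes: Sequence[GeneRecord]
) -> tuple[list[Read], dict[str, int]]:
    """Draw reads from the gene pool; returns (reads, per-gene truth counts).

    Fragment starts are uniform over each gene, per-gene fragment counts are
    Poisson at the configured abundance, substitution errors are applied per
    fragment, and each fragment is emitted with its (possibly Zipf) copy
    multiplicity.  The truth table counts every emitted read by source gene;
    its total always equals the number of reads returned.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = set(config.abundances) - set(by_id)
    if unknown:
        raise ValueError(f"abundance given for unknown gene(s): {sorted(unknown)}")
    if all(a == 0 for a in config.abundances.values()):
        raise ValueError("all abundances are zero; nothing to simulate")
    rng = np.random.default_rng(config.seed)
    reads: list[Read] = []
    truth: dict[str, int] = {g: 0 for g in config.abundances}
    for gene_id in sorted(config.abundances):
        gene = by_id[gene_id]
        if gene.length < config.read_length:
            raise ValueError(
                f"gene {gene_id!r} shorter than read length {config.read_length}"
            )
        n_frag = int(rng.poisson(config.abundances[gene_id]))
        for i in range(n_frag):
            start = int(rng.integers(0, gene.length - config.read_length + 1))
            frag = np.array(list(gene.bases[start : start + config.read_length]))
            if config.error_rate > 0:
                frag = _diverge(rng, frag, config.error_rate)
            seq = "".join(frag)
            copies = 1
            if config.duplication_skew is not None:
                copies = min(int(rng.zipf(config.duplication_skew)), MAX_COPY)
            for j in range(copies):
                reads.append(
                    Read(
                        f"{gene_id}.f{i}.c{j}",
                        seq,
                        _qualities(rng, config.read_length, config.quality),
                    )
                )
                truth[gene_id] += 1
    assert sum(truth.values()) == len(reads)
    return reads, truth
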