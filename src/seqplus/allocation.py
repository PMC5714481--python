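"""Allocate shared reads among paralogous genes.

Reads that tie across paralogs are divided in proportion to each gene's
uniquely-assigned read count: for two genes,

    P_1 = N_U.1 / (N_U.1 + N_U.2)

with an equal split when both unique counts are zero (identical paralogs),
an optional per-gene pseudocount, and an optional per-kilobase length
standardisation SN_U.i = 1000 N_U.i / L_i for genes of unequal length.

For families of three or more genes the shared sets are resolved
*progressively*: first the sets shared by two genes, then by three, and so
on up to the largest set.  At each stage every set's member proportions are
computed from the counts accumulated so far, and the set's reads are added
to the members accordingly.  This tree-free procedure reproduces the result
of allocating along the paralogs' phylogeny without building any tree.

Alternative weightings divide a read by relative bit score
(P_i = BitScore_i / ΣBitScore) or by inverse e-value (P_i ∝ min(E)/E_i);
the e-value scheme is the more sharply biased toward the best hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from seqplus.matcher import GeneRecord, MatchTable

Subset = frozenset[str]

CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class AllocationParams:
    """Tunable knobs of the unique-count proportional scheme.

    pseudocount_eps
        Per-gene pseudocount added to every numerator (and F times to the
        denominator).  Default 0: the plain-ratio arithmetic with an explicit
        equal split on an all-zero subset.  Set 0.01 for the pseudocounted
        variant.
    length_normalize
        Replace N_U.i by 1000 N_U.i / L_i when forming proportions.  None
        (default) selects it automatically: on for two-member families, off
        for larger ones (which are assumed roughly length-matched).
    scheme
        "unique_counts" (the progressive scheme), "bitscore", or "evalue".
    """

    pseudocount_eps: float = 0.0
    length_normalize: bool | None = None
    scheme: str = "unique_counts"

    def __post_init__(self) -> None:
        if self.pseudocount_eps < 0:
            raise ValueError("pseudocount_eps must be >= 0")
        if self.scheme not in ("unique_counts", "bitscore", "evalue"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class FamilyState:
    """Accumulated unique-equivalent counts N_U.i and lengths L_i per gene."""

    counts: dict[str, float]
    lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for gene {g!r}")

    def effective(self, gene: str, normalize: bool) -> float:
        if not normalize:
            return self.counts[gene]
        if self.lengths is None or gene not in self.lengths:
            raise ValueError(f"length normalization requested but no length for {gene!r}")
        return 1000.0 * self.counts[gene] / self.lengths[gene]


@dataclass
class AllocationResult:
    """Final allocated counts N_i plus the per-set proportion vectors.

    ``stage_states`` snapshots the accumulated counts after each subset-size
    stage of the progressive pass (key = subset size processed), exposing the
    intermediate unique-equivalent counts.
    """

    counts: dict[str, float]
    proportions: dict[Subset, dict[str, float]] = field(default_factory=dict)
    stage_states: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.counts.values())


def _subset_proportions(
    state: FamilyState,
    subset: Sequence[str],
    eps: float,
    normalize: bool,
) -> dict[str, float]:
    eff = {g: state.effective(g, normalize) for g in subset}
    total = sum(eff.values())
    f = len(subset)
    if eps == 0.0 and total == 0.0:
        return {g: 1.0 / f for g in subset}  # identical-paralog equal split
    denom = f * eps + total
    if denom == 0.0:
        return {g: 1.0 / f for g in subset}
    return {g: (eps + eff[g]) / denom for g in subset}


def proportion_two(
    nu1: float,
    nu2: float,
    params: AllocationParams | None = None,
    lengths: tuple[int, int] | None = None,
) -> float:
    """Share of an equally-matching read assigned to gene 1 of a pair.

    With no pseudocount this is nu1/(nu1+nu2), and exactly 1/2 when both
    unique counts are zero.  With ``lengths`` given and length normalization
    active, counts are standardised to per-kilobase rates first.
    """
    params = params or AllocationParams()
    if nu1 < 0 or nu2 < 0:
        raise ValueError("unique counts must be >= 0")
    normalize = params.length_normalize
    if normalize is None:
        normalize = lengths is not None
    state = FamilyState(
        {"g1": float(nu1), "g2": float(nu2)},
        {"g1": lengths[0], "g2": lengths[1]} if lengths else None,
    )
    return _subset_proportions(state, ("g1", "g2"), params.pseudocount_eps, normalize)[
        "g1"
    ]


def progressive_allocate(
    family: FamilyState,
    shared_sets: Mapping[Subset | Iterable[str], float],
    params: AllocationParams | None = None,
) -> AllocationResult:
    """Resolve all shared-read sets of one family, smallest subsets first.

    ``shared_sets`` maps each tied-best gene subset to its shared read count
    (copy numbers already folded in).  Subsets are processed in stages of
    increasing size; within a stage every subset's proportions are computed
    from the stage-start accumulated counts, so the order of same-size
    subsets is immaterial.  Returns the final per-gene counts, the
    proportion vector used for every subset, and the accumulated counts
    after each stage.
    """
    params = params or AllocationParams()
    shared: dict[Subset, float] = {}
    for subset, count in shared_sets.items():
        fs = frozenset(subset)
        if len(fs) < 2:
            raise ValueError(f"shared set {sorted(fs)} has fewer than 2 genes")
        unknown = fs - family.counts.keys()
        if unknown:
            raise ValueError(f"shared set names unknown gene(s): {sorted(unknown)}")
        if count < 0:
            raise ValueError("shared counts must be >= 0")
        shared[fs] = shared.get(fs, 0.0) + float(count)

    normalize = params.length_normalize
    if normalize is None:
        normalize = len(family.counts) == 2 and family.lengths is not None

    acc = FamilyState(dict(family.counts), family.lengths)
    result = AllocationResult(counts=acc.counts)
    for size in sorted({len(s) for s in shared}):
        stage_sets = [s for s in shared if len(s) == size]
        snapshot = FamilyState(dict(acc.counts), family.lengths)
        increments: dict[str, float] = {}
        for subset in sorted(stage_sets, key=lambda s: tuple(sorted(s))):
            props = _subset_proportions(
                snapshot, sorted(subset), params.pseudocount_eps, normalize
            )
            result.proportions[subset] = props
            for g, p in props.items():
                increments[g] = increments.get(g, 0.0) + shared[subset] * p
        for g, inc in increments.items():
            acc.counts[g] += inc
        result.stage_states[size] = dict(acc.counts)

    expected = sum(family.counts.values()) + sum(shared.values())
    assert abs(result.total - expected) <= CONSERVATION_TOL * max(1.0, expected)
    return result


def allocate_bitscore(bitscores: Mapping[str, float]) -> dict[str, float]:
    """P_i = BitScore_i / Σ BitScore_j; tends to be close to an equal split."""
    if any(b <= 0 for b in bitscores.values()):
        raise ValueError("bit scores must be > 0")
    total = sum(bitscores.values())
    return {g: b / total for g, b in bitscores.items()}


EVALUE_FLOOR = 1e-180


def allocate_evalue(evalues: Mapping[str, float]) -> dict[str, float]:
    """P_i ∝ min(E)/E_i; the best (smallest e-value) hit takes the largest share.

    E-values reported as 0 are clamped to a floor of 1e-180 before the ratio.
    """
    if any(e < 0 for e in evalues.values()):
        raise ValueError("e-values must be >= 0")
    clamped = {g: max(e, EVALUE_FLOOR) for g, e in evalues.items()}
    emin = min(clamped.values())
    weights = {g: emin / e for g, e in clamped.items()}
    total = sum(weights.values())
    if total == 0:
        raise ValueError("all e-value weights vanished")
    return {g: w / total for g, w in weights.items()}


@dataclass
class GenomeAllocation:
    """Allocation of a whole MatchTable: one result per paralog family."""

    families: dict[Subset, AllocationResult]
    unmapped: float

    @property
    def counts(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for res in self.families.values():
            out.update(res.counts)
        return out

    @property
    def total_mapped(self) -> float:
        return sum(res.total for res in self.families.values())

    def to_tsv(self, out: IO[str]) -> None:
        out.write("family\tgene\tcount\n")
        for fam in sorted(self.families, key=lambda f: tuple(sorted(f))):
            fam_id = ",".join(sorted(fam))
            for g in sorted(self.families[fam].counts):
                out.write(f"{fam_id}\t{g}\t{self.families[fam].counts[g]:.5f}\n")


def _connected_components(edges: Iterable[Subset], nodes: Iterable[str]) -> list[set[str]]:
    parent: dict[str, str] = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in edges:
        it = iter(edge)
        first = find(next(it))
        for other in it:
            parent[find(other)] = first
    comps: dict[str, set[str]] = {}
    for n in parent:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def allocate_all(
    table: MatchTable,
    genes: Sequence[GeneRecord] | Mapping[str, int] | None = None,
    params: AllocationParams | None = None,
) -> GenomeAllocation:
    """Allocate every read of a classified MatchTable.

    Genes are partitioned into paralog families as the connected components
    of the co-best-hit graph (genes linked whenever some read ties across
    them).  Within each family, uniquely matching reads (weighted by copy
    number) seed the unique counts; shared reads are grouped by their exact
    tied gene set and resolved by the progressive scheme, or split per read
    by bit score / e-value when that scheme is selected.  Reads with no best
    hit are tallied as unmapped.
    """
    params = params or AllocationParams()
    lengths: dict[str, int] | None = None
    if genes is not None:
        if isinstance(genes, Mapping):
            lengths = dict(genes)
        else:
            lengths = {g.gene_id: g.length for g in genes}

    seen_genes: set[str] = set()
    for e in table.entries:
        seen_genes |= e.gene_set
    shared_edges = [e.gene_set for e in table.entries if len(e.gene_set) > 1]
    families = _connected_components(shared_edges, seen_genes)

    fam_of: dict[str, Subset] = {}
    for comp in families:
        key = frozenset(comp)
        for g in comp:
            fam_of[g] = key

    uniques: dict[Subset, dict[str, float]] = {
        frozenset(c): {g: 0.0 for g in c} for c in families
    }
    shared: dict[Subset, dict[Subset, float]] = {frozenset(c): {} for c in families}
    weighted: dict[Subset, dict[str, float]] = {
        frozenset(c): {g: 0.0 for g in c} for c in families
    }
    unmapped = 0.0
    for e in table.entries:
        if e.is_unmapped:
            unmapped += e.copy_number
            continue
        fam = fam_of[next(iter(e.gene_set))]
        assert all(fam_of[g] == fam for g in e.gene_set)  # families are components
        if e.is_unique:
            uniques[fam][next(iter(e.gene_set))] += e.copy_number
        elif params.scheme == "unique_counts":
            key = e.gene_set
            shared[fam][key] = shared[fam].get(key, 0.0) + e.copy_number
        elif params.scheme == "bitscore":
            props = allocate_bitscore({h.gene_id: h.score for h in e.best_hits})
            for g, p in props.items():
                weighted[fam][g] += e.copy_number * p
        else:  # evalue
            evs = {h.gene_id: h.evalue for h in e.best_hits}
            if any(v is None for v in evs.values()):
                raise ValueError("e-value scheme requires hits with e-values")
            props = allocate_evalue(evs)  # type: ignore[arg-type]
            for g, p in props.items():
                weighted[fam][g] += e.copy_number * p

    results: dict[Subset, AllocationResult] = {}
    for comp in families:
        key = frozenset(comp)
        state = FamilyState(
            dict(uniques[key]),
            {g: lengths[g] for g in comp} if lengths is not None else None,
        )
        res = progressive_allocate(state, shared[key], params)
        if params.scheme != "unique_counts":
            for g, w in weighted[key].items():
                res.counts[g] += w
        results[key] = res

    total = sum(r.total for r in results.values()) + unmapped
    assert abs(total - table.total_reads) <= CONSERVATION_TOL * max(1.0, total)
    return GenomeAllocation(results, unmapped)
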