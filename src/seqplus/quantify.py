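"""Expression table: Count, Count/Kb and FPKM per reference gene.

Count/Kb is the allocated read count standardised to a 1-kb transcript,
1000·N/L; FPKM further scales it per million mapped reads,
N·1e9/(L·total_mapped).  The mapped-read total defaults to the sum of
allocated counts over all genes (unmapped reads excluded) and can be
overridden.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from seqplus.matcher import GeneRecord

COLUMNS = ["Gene ID", "SeqLen", "Count", "Count/Kb", "FPKM"]


def count_per_kb(count: float, length: int) -> float:
    """Reads per kilobase of transcript: 1000·count/length."""
    if length <= 0:
        raise ValueError("gene length must be > 0")
    return 1000.0 * count / length


def fpkm(count: float, length: int, total_mapped: float) -> float:
    """Reads per kilobase per million mapped reads: count·1e9/(length·total)."""
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    return count * 1e9 / (length * total_mapped)


def expression_table(
    counts: Mapping[str, float],
    genes: Sequence[GeneRecord],
    total_mapped: float | None = None,
) -> pd.DataFrame:
    """One row per reference gene, sorted by gene id, zero-count genes included.

    ``counts`` maps gene id to its allocated (possibly fractional) read
    count; every counted gene must exist in the reference.
    """
    lengths = {g.gene_id: g.length for g in genes}
    missing = set(counts) - set(lengths)
    if missing:
        raise ValueError(f"allocated gene(s) missing from reference: {sorted(missing)}")
    if total_mapped is None:
        total_mapped = sum(counts.values())
    rows = []
    for gene_id in sorted(lengths):
        n = float(counts.get(gene_id, 0.0))
        length = lengths[gene_id]
        rows.append(
            {
                "Gene ID": gene_id,
                "SeqLen": length,
                "Count": n,
                "Count/Kb": count_per_kb(n, length),
                "FPKM": fpkm(n, length, total_mapped) if total_mapped > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    """Write the table as TSV: counts at 5 decimals, Count/Kb and FPKM at 3."""
    out = df.copy()
    out["Count"] = out["Count"].map(lambda v: f"{v:.5f}")
    out["Count/Kb"] = out["Count/Kb"].map(lambda v: f"{v:.3f}")
    out["FPKM"] = out["FPKM"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)
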