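# Methods

## Deduplicated read storage (FASTA+/FASTQ+)

`collapse` builds an exact-match dictionary over full, upper-cased base
strings.  Two reads merge only if their sequences are byte-identical; a
read that is a prefix of a longer one stays distinct.  This is deliberate:
the format is a *lossless* re-encoding of the sequence multiset, and any
near-duplicate merging would turn it into lossy compression.  The whole
unique-sequence dictionary is held in memory, which is the intended
desk-scale operating point (tens of millions of short reads on an ordinary
workstation); no external-memory path is provided.

Collapsed records are written in descending copy number, ties broken by
the lexicographic order of the bases, and assigned ids `S1, S2, …` in that
order.  Identical input multisets therefore produce byte-identical output
regardless of read order, at the cost of not retaining original read ids —
those, and the individual per-read quality vectors, are the two documented
lossy fields.  `expand_plus` inverts the collapse up to exactly those
fields.

Per-site quality of a collapsed record is the flat arithmetic mean over
all original copies.  When copies arrive already collapsed (a FASTQ+ file
re-collapsed with new reads), the stored mean is treated as the mean of
its `copy_number` originals, i.e. copies always weight the mean.  Encoding
rounds half-up to the nearest integer Phred value; the unrounded means are
kept in memory and only rounded at write time.  Quality handling is fixed
at Phred+33; characters below `!` raise a parse error rather than being
silently mis-decoded as Phred+64.

The `size_ratio` statistic is collapsed plain-text bytes over original
plain-text bytes (headers included, FASTQ+ compared against FASTQ and
FASTA+ against FASTA).  Its monotone degradation with per-base error rate
— errors split identical fragments apart — is asserted on seeded simulated
data.

## The k-mer matcher

The paper-scale workflow delegates read matching to BLAST; this package
includes a small self-contained substitute so the pipeline runs end to end
without external binaries.  Genes are indexed by exact k-mers on both
strands (default k = 15).  A read's k-mers nominate (gene, strand,
diagonal) placements; each placement is scored ungapped over the full
read/gene overlap, the score being the count of matching bases.  Per gene
only the best placement is kept (repeats within one gene collapse to one
hit, since allocation operates on gene *sets*).  A hit is retained when
the read has at least `min_in_gene` bases inside the gene (default 25), so
a read overhanging a gene's 3' end — e.g. 36 nt inside, 14 nt of
downstream sequence — still counts toward that gene.

Classification is strict: a read is *unique* iff exactly one gene attains
the top score, and *shared* iff two or more tie exactly.  For BLAST-style
tabular input (outfmt 6) the score is the bit score and a tie additionally
requires exact e-value equality.  Ungapped extension is a deliberate
limitation: the allocation mathematics only consumes gene sets and scores,
and indel-tolerant alignment would add complexity without changing any
downstream quantity.  The error model of the simulator is correspondingly
substitution-only.

## Allocation

Unique matches, weighted by copy numbers, seed each gene's
unique-equivalent count.  Genes are partitioned into families as connected
components of the co-best-hit graph, so a shared read can never straddle
two families (asserted).  Shared reads are grouped by their exact tied
gene set and resolved progressively by increasing set size.

Two numerical choices matter:

- **Stage-batched updates.**  Within one stage (all sets of one size),
  every set's proportions are computed from the counts as they stood at
  the start of the stage, and the additions are applied together
  afterwards.  This makes the result invariant to the enumeration order of
  same-size sets, which a sequential update would not be.
- **Pseudocount default ε = 0** with an explicit equal split when a set's
  accumulated counts are all zero.  The pseudocounted form
  (ε + N)/(Fε + ΣN) is available via `AllocationParams(pseudocount_eps=0.01)`
  but is off by default because the plain-ratio arithmetic is what the
  worked reference values use; the two variants differ in the fourth
  decimal and are mutually exclusive, so the choice is exposed rather than
  hidden.

Length standardisation (per-kilobase unique counts, SN = 1000·N/L) defaults
to *auto*: applied for two-member families, skipped for larger ones, which
are treated as roughly length-matched; both behaviours can be forced.  The
rationale is that the progressive F-member arithmetic is defined on
equal-footing counts, while the two-member formula has a well-defined
length-corrected form.

Bit-score and e-value weighting are per-read schemes: each shared read is
split by `P_i = BitScore_i/ΣBitScore` or `P_i ∝ min(E)/E_i` directly,
without the progressive pass.  E-values of zero are clamped to 1e-180
before forming ratios.  The e-value scheme is provably more concentrated
on the best hit than the bit-score scheme whenever the two rank hits the
same way with a nontrivial gap; the test suite asserts this on fixed
score vectors.

Counts are doubles throughout; read conservation
(Σ N_i + unmapped = Σ copy numbers) is asserted at 1e-9 relative tolerance
after every allocation, and reports print 5 decimals.

## Expression table

`Count/Kb = 1000·N/L` and `FPKM = N·10⁹/(L·total_mapped)`.  The FPKM
denominator defaults to the sum of allocated counts over all genes —
unmapped reads are excluded, on the reading that "mapped reads" means
reads that were actually assigned — and can be overridden
(`--total-mapped`) for compatibility with pipelines that normalise by
total library size.  Every reference gene gets a row (zero-count genes
included), rows are sorted by gene id, and the FPKM/Count-per-Kb ratio is
constant across rows of one run.

## Synthetic data

The generator emulates the regimes the tool targets, with ground truth for
recovery tests:

- **Families**: a uniform-random ancestor with members derived by
  independent per-site substitution at the chosen divergence (0 gives
  identical paralogs, the degenerate equal-split case), or the segmented
  three-gene topology — conserved middle third in all members, first third
  identical in members two and three, fully diverged last third — which
  guarantees a large population of shared reads.
- **Reads**: per-gene fragment counts are Poisson at the configured
  abundance, start positions uniform, substitution errors applied per
  fragment *before* replication so that duplicated copies stay identical,
  as PCR duplicates do.  Each fragment's multiplicity is Zipf-distributed
  (exponent configurable; clipped at 5,000 copies to keep files desk-scale
  while preserving the one-dominant-read shape).  Quality vectors are
  drawn per copy: flat around Phred 38 in the high-quality regime, or
  decaying from ~35 to ~15 along the read with larger spread in the poor
  regime.

What the simulator does **not** model: indels (the matcher is ungapped by
design), coverage bias, adapter contamination, paired-end structure (each
mate of a pair is processed as an independent file throughout the
package), or rRNA contamination.  Passing recovery tests therefore show
that the allocation arithmetic is correct and unbiased under uniform
coverage with substitution noise — not that quantification is robust to
every artefact of real libraries.

Default study conditions used by the tests: families of 2–3 genes of
400–900 nt, 50-nt reads, per-gene expected fragment counts in the
hundreds-to-thousands (≥10,000 total reads for the conservation checks),
error rates 0–5%, Zipf exponent 2.0 when duplication is on.  Recovery is
asserted within 3 Poisson standard errors of each gene's true read count
on error-free reads; all stochastic tests run on fixed seeds.

## Known limitations

- Exact-score ties only: near-ties (one mismatch apart) are treated as a
  unique match, so the shared-read population is sensitive to read quality.
  `min_in_gene` and k are exposed for tuning.
- In-memory processing throughout; no streaming or disk-backed index.
- The allocation is a single-pass counting scheme, not an EM or
  likelihood-based reassignment; it is deterministic and conservative but
  cannot correct a misleading unique-count profile (e.g. strongly
  non-uniform coverage inside one paralog).
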