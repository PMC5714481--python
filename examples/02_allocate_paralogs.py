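"""Allocate reads shared among paralogous genes.

Two classic situations:

1. A three-gene family where 20 reads tie between genes B and C and 23 tie
   across all three.  The progressive scheme resolves the pairwise set
   first, then uses the updated unique-equivalent counts for the triple.

2. A two-paralog pair (modelled on the E. coli cold-shock genes cspF/cspH):
   291 and 86 reads resolve uniquely once better-scoring matches are folded
   in, and 12 exact ties are split in proportion 291:86.
"""

from seqplus import (
    FamilyState,
    Hit,
    MatchEntry,
    MatchTable,
    allocate_all,
    progressive_allocate,
    proportion_two,
)

# --- three-gene family -----------------------------------------------------
state = FamilyState({"A": 7.0, "B": 6.0, "C": 12.0})
shared = {frozenset("BC"): 20.0, frozenset("ABC"): 23.0}
res = progressive_allocate(state, shared)

print("three-gene family (uniques A:7 B:6 C:12, shared BC:20 ABC:23)")
after2 = res.stage_states[2]
print(f"  after the pairwise stage: B={after2['B']:.5f}  C={after2['C']:.5f}")
props = res.proportions[frozenset("ABC")]
print(
    "  triple-set proportions:   "
    + "  ".join(f"P_{g}={props[g]:.5f}" for g in "ABC")
)
print(
    "  final allocated counts:   "
    + "  ".join(f"N_{g}={res.counts[g]:.5f}" for g in "ABC")
)

# --- two-paralog pair ------------------------------------------------------
table = MatchTable(
    [
        MatchEntry("unique_F", 264, [Hit("cspF", 98.0)]),
        MatchEntry("unique_H", 58, [Hit("cspH", 98.0)]),
        MatchEntry("better_F", 27, [Hit("cspF", 95.0)]),
        MatchEntry("better_H", 28, [Hit("cspH", 95.0)]),
        MatchEntry("ties", 12, [Hit("cspF", 90.0), Hit("cspH", 90.0)]),
    ]
)
alloc = allocate_all(table, {"cspF": 213, "cspH": 213})
p = proportion_two(291, 86)
print("\ncold-shock paralog pair (uniques 291 vs 86, 12 exact ties)")
print(f"  tie-split proportions:  {p:.4f} / {1 - p:.4f}")
print(f"  final counts:           cspF={alloc.counts['cspF']:.4f}  "
      f"cspH={alloc.counts['cspH']:.4f}")
print(f"  reads conserved:        {sum(alloc.counts.values()):.4f} == 389")
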