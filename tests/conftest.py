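import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from seqplus.allocation import FamilyState
from seqplus.matcher import Hit, MatchEntry, MatchTable


@pytest.fixture
def three_gene_family():
    """The segmented three-paralog worked example: uniques A:7, B:6, C:12,
    20 reads shared by {B,C} and 23 shared by {A,B,C}."""
    state = FamilyState({"A": 7.0, "B": 6.0, "C": 12.0})
    shared = {frozenset("BC"): 20.0, frozenset("ABC"): 23.0}
    return state, shared


@pytest.fixture
def csp_match_table():
    """The cspF/cspH cold-shock paralog pair encoded as a classified table:
    264 reads unique to cspF, 58 to cspH, 27 shared reads scoring cspF
    higher, 28 scoring cspH higher, and 12 exact (bitscore, e-value) ties."""
    return MatchTable(
        [
            MatchEntry("u_cspF", 264, [Hit("cspF", 98.0, evalue=1e-20)]),
            MatchEntry("u_cspH", 58, [Hit("cspH", 98.0, evalue=1e-20)]),
            MatchEntry("b_cspF", 27, [Hit("cspF", 95.0, evalue=1e-18)]),
            MatchEntry("b_cspH", 28, [Hit("cspH", 95.0, evalue=1e-18)]),
            MatchEntry(
                "tie",
                12,
                [Hit("cspF", 90.0, evalue=1e-15), Hit("cspH", 90.0, evalue=1e-15)],
            ),
        ]
    )
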