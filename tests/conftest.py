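"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
codon table is written out by hand, and mutant proteins are obtained by
rebuilding the complete mutant cDNA and translating it codon by codon,
so they can serve as brute-force cross-checks of the rule-based
consequence derivations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from splicevar import JunctionEvidence, make_pnkp_like_model

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# hand-written standard genetic code (independent of the implementation)
_T = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_B = "TCAG"
for i1, b1 in enumerate(_B):
    for i2, b2 in enumerate(_B):
        for i3, b3 in enumerate(_B):
            _T[b1 + b2 + b3] = _AA[16 * i1 + 4 * i2 + i3]


def oracle_translate(seq: str) -> str:
    """Codon-by-codon lookup translation; stops at and includes '*'."""
    seq = seq.upper().replace("U", "T")
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = _T[seq[i : i + 3]]
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


def oracle_mutant_protein(model, event: dict) -> str:
    """Protein of the aberrant transcript, by full rebuild + translation.

    ``event``: {"kind": "skip", "exon": k} or
    {"kind": "retention", "intron": j, "snv": optional (c_pos, alt)}.
    """
    cds = model.cds
    if event["kind"] == "skip":
        cs, ce = model.exon_c_range(event["exon"])
        mutant = cds[: cs - 1] + cds[ce:]
    elif event["kind"] == "retention":
        if event.get("snv"):
            c_pos, alt = event["snv"]
            cds = cds[: c_pos - 1] + alt + cds[c_pos:]
        P = model.exons[event["intron"] - 1].c_end
        mutant = cds[:P] + model.intron_seq(event["intron"]) + cds[P:]
    else:
        raise ValueError(event["kind"])
    return oracle_translate(mutant)


@pytest.fixture(scope="session")
def pnkp_model():
    return make_pnkp_like_model(seed=0)


@pytest.fixture
def worked_evidence():
    """Junction counts and coverage printed for the exon 11 event."""
    return JunctionEvidence(
        inclusion_up=30, inclusion_down=33, skip=24,
        exon_cov=69, intron_cov=11, intron_length=120, library_size=10_000_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# minimal hand-written PDB fixture: 3 residues, one with altloc A/B
PDB_FIXTURE = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA AGLY A   2       2.000   1.000   0.000  0.60  0.00           C
ATOM      4  CA BGLY A   2       9.000   9.000   9.000  0.40  0.00           C
ATOM      5  CA  SER A   3       3.000   3.000   3.000  1.00  0.00           C
ATOM      6  CB  SER A   3       3.500   3.000   3.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_FIXTURE)
    return path
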