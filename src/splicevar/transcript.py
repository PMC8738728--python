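"""Coding-transcript models and exact CDS coordinate arithmetic.

A :class:`TranscriptModel` describes one coding transcript as an ordered
list of exons with 1-based, closed coding (c.) coordinates, optional exon
and intron nucleotide sequences, and the standard mapping between
c.-positions, codons and protein residues.  All downstream consequence and
splicing arithmetic is performed in this coordinate system; genomic strand
is resolved once at parse time and never seen again.

Internally positions are 0-based half-open; every public surface (I/O,
HGVS codes, error messages) speaks 1-based closed c.-coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "ExonSpec",
    "TranscriptModel",
    "c_to_codon",
    "translate",
    "transcript_from_config",
    "transcript_from_gtf",
]

_STOP_CODONS = frozenset(s.replace("U", "T") for s in standard_dna_table.stop_codons)
_CODON_TABLE = {k.replace("U", "T"): v for k, v in standard_dna_table.forward_table.items()}

# Three-letter amino-acid codes used on HGVS surfaces (IUPAC), '*' for stop.
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "*",
}

_VALID_NT = frozenset("ACGTU")


def c_to_codon(c_pos: int) -> tuple[int, int]:
    """Map a 1-based coding position to (codon_index, offset_in_codon).

    ``codon_index`` is 1-based (codon 1 is the initiator ATG) and
    ``offset_in_codon`` is 1, 2 or 3.
    """
    if c_pos < 1:
        raise ValueError(f"c.-position must be >= 1, got {c_pos}")
    return (c_pos - 1) // 3 + 1, (c_pos - 1) % 3 + 1


def translate(cdna: str) -> str:
    """Translate a coding sequence codon by codon.

    Stops at and includes the first stop codon (reported as ``*``); a
    trailing partial codon is ignored.  Accepts DNA or RNA alphabet.
    """
    if len(cdna) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = cdna.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    seq = seq.replace("U", "T")
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            out.append("*")
            break
        out.append(_CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class ExonSpec:
    """One exon's coding span, 1-based and closed."""

    index: int
    c_start: int
    c_end: int

    def __post_init__(self) -> None:
        if self.c_end < self.c_start:
            raise ValueError(
                f"exon {self.index}: c_end ({self.c_end}) < c_start ({self.c_start})"
            )

    @property
    def span(self) -> int:
        return self.c_end - self.c_start + 1


@dataclass
class TranscriptModel:
    """Exon/intron layout of a coding transcript in c.-coordinates.

    Parameters
    ----------
    id:
        Transcript identifier (e.g. a RefSeq accession).
    exons:
        Ordered exon coding spans; exon k+1 must start at exon k's
        ``c_end + 1``.
    cds_start_offset:
        Transcript bases preceding the A of the initiator ATG.  When
        non-zero, exon 1's sequence carries that many extra leading
        (untranslated) bases; coding spans themselves never include UTR.
    exon_seqs / intron_seqs:
        Optional nucleotide sequences.  ``intron_seqs[i]`` lies between
        exon ``i+1`` and exon ``i+2`` (0-based list, introns numbered
        1..n_exons-1).
    strand:
        Annotation only; all arithmetic is in transcript orientation.
    """

    id: str
    exons: list[ExonSpec]
    cds_start_offset: int = 0
    exon_seqs: list[str] | None = None
    intron_seqs: list[str] | None = None
    strand: str = "+"

    _cds: str | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        if self.cds_start_offset < 0:
            raise ValueError(f"transcript {self.id}: negative cds_start_offset")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-'")
        expected_start = 1
        for k, exon in enumerate(self.exons, start=1):
            if exon.index != k:
                raise ValueError(
                    f"transcript {self.id}: exon at list position {k} has index {exon.index}"
                )
            if exon.c_start != expected_start:
                raise ValueError(
                    f"transcript {self.id}: exon {k} starts at c.{exon.c_start}, "
                    f"expected c.{expected_start} (contiguous coding coordinates)"
                )
            expected_start = exon.c_end + 1
        if self.exon_seqs is not None:
            self.exon_seqs = [s.upper() for s in self.exon_seqs]
            if len(self.exon_seqs) != len(self.exons):
                raise ValueError(
                    f"transcript {self.id}: {len(self.exon_seqs)} exon sequences "
                    f"for {len(self.exons)} exons"
                )
            for k, (exon, seq) in enumerate(zip(self.exons, self.exon_seqs), start=1):
                expected = exon.span
                if k == 1:
                    expected += self.cds_start_offset
                if k == 1 and len(self.exons) == 1:
                    if len(seq) < expected:
                        raise ValueError(
                            f"transcript {self.id}: exon 1 sequence shorter than its span"
                        )
                elif k == len(self.exons):
                    # trailing bases after the coding span are 3' UTR
                    if len(seq) < expected:
                        raise ValueError(
                            f"transcript {self.id}: exon {k} sequence shorter than its span"
                        )
                elif len(seq) != expected:
                    raise ValueError(
                        f"transcript {self.id}: exon {k} sequence length {len(seq)} "
                        f"!= span {expected}"
                    )
            cds = self.cds
            if not cds.startswith("ATG"):
                raise ValueError(f"transcript {self.id}: CDS does not start with ATG")
            if "*" not in translate(cds):
                raise ValueError(f"transcript {self.id}: CDS contains no stop codon")
        if self.intron_seqs is not None:
            self.intron_seqs = [s.upper() for s in self.intron_seqs]
            if len(self.intron_seqs) != len(self.exons) - 1:
                raise ValueError(
                    f"transcript {self.id}: {len(self.intron_seqs)} intron sequences "
                    f"for {len(self.exons)} exons"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_length(self) -> int:
        return self.exons[-1].c_end

    def exon_c_range(self, exon_index: int) -> tuple[int, int]:
        """Closed 1-based c.-interval of an exon."""
        if not 1 <= exon_index <= self.n_exons:
            raise IndexError(
                f"transcript {self.id}: exon index {exon_index} out of range "
                f"(1..{self.n_exons})"
            )
        exon = self.exons[exon_index - 1]
        return exon.c_start, exon.c_end

    def intron_flanks(self, intron_index: int) -> tuple[int, int]:
        """c.-positions flanking an intron: (last exonic base, next exonic base)."""
        if not 1 <= intron_index <= self.n_introns:
            raise IndexError(
                f"transcript {self.id}: intron index {intron_index} out of range "
                f"(1..{self.n_introns})"
            )
        return self.exons[intron_index - 1].c_end, self.exons[intron_index].c_start

    # -- sequences ------------------------------------------------------

    @property
    def cds(self) -> str:
        """Coding sequence (concatenated coding exon bases)."""
        if self.exon_seqs is None:
            raise ValueError(f"transcript {self.id}: no sequences supplied")
        if self._cds is None:
            parts = []
            for k, (exon, seq) in enumerate(zip(self.exons, self.exon_seqs), start=1):
                start = self.cds_start_offset if k == 1 else 0
                parts.append(seq[start : start + exon.span])
            self._cds = "".join(parts)
        return self._cds

    @property
    def protein(self) -> str:
        """Reference protein including the terminal '*'."""
        return translate(self.cds)

    def residue(self, index: int) -> str:
        """One-letter amino acid at a 1-based residue index."""
        prot = self.protein
        if not 1 <= index <= len(prot):
            raise IndexError(
                f"transcript {self.id}: residue {index} out of range (1..{len(prot)})"
            )
        return prot[index - 1]

    def intron_seq(self, intron_index: int) -> str:
        if self.intron_seqs is None:
            raise ValueError(f"transcript {self.id}: no intron sequences supplied")
        if not 1 <= intron_index <= self.n_introns:
            raise IndexError(
                f"transcript {self.id}: intron index {intron_index} out of range "
                f"(1..{self.n_introns})"
            )
        return self.intron_seqs[intron_index - 1]


# ---------------------------------------------------------------------------
# constructors from external representations
# ---------------------------------------------------------------------------

def transcript_from_config(config: dict) -> TranscriptModel:
    """Build a model from a self-contained structured description.

    Expected keys: ``id``, ``exon_lengths`` (coding spans, 5'→3'), and
    optionally ``exon_seqs``, ``intron_seqs``, ``cds_start_offset``,
    ``strand``.  Produces the same values as the GTF+FASTA path.
    """
    lengths = list(config["exon_lengths"])
    exons = []
    start = 1
    for k, length in enumerate(lengths, start=1):
        exons.append(ExonSpec(index=k, c_start=start, c_end=start + length - 1))
        start += length
    return TranscriptModel(
        id=config["id"],
        exons=exons,
        cds_start_offset=int(config.get("cds_start_offset", 0)),
        exon_seqs=config.get("exon_seqs"),
        intron_seqs=config.get("intron_seqs"),
        strand=config.get("strand", "+"),
    )


def transcript_from_gtf(gtf_path: str, fasta_path: str, transcript_id: str) -> TranscriptModel:
    """Build a model from a GTF (exon + CDS features) and a genome FASTA.

    ``transcript_id`` is a required selector; an absent id is an error,
    never a silent first match.  Minus-strand transcripts are normalized to
    transcript orientation here; downstream code never sees strand.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exon_feats = [
        f for f in db.features_of_type("exon")
        if transcript_id in f.attributes.get("transcript_id", [])
    ]
    cds_feats = [
        f for f in db.features_of_type("CDS")
        if transcript_id in f.attributes.get("transcript_id", [])
    ]
    if not exon_feats:
        raise ValueError(f"transcript_id {transcript_id!r} not found in {gtf_path}")
    if not cds_feats:
        raise ValueError(f"transcript {transcript_id!r} has no CDS features in {gtf_path}")
    strands = {f.strand for f in exon_feats}
    if len(strands) != 1:
        raise ValueError(f"transcript {transcript_id!r}: inconsistent strands {strands}")
    strand = strands.pop()

    genome = Fasta(str(fasta_path), as_raw=True, rebuild=False)

    def fetch(f):
        seq = str(genome[f.seqid][f.start - 1 : f.end]).upper()
        return _revcomp(seq) if strand == "-" else seq

    reverse = strand == "-"
    exon_feats.sort(key=lambda f: f.start, reverse=reverse)
    cds_feats.sort(key=lambda f: f.start, reverse=reverse)

    # match CDS pieces to exons by genomic overlap
    cds_by_exon: dict[int, object] = {}
    for c in cds_feats:
        hits = [
            i for i, e in enumerate(exon_feats)
            if c.start >= e.start and c.end <= e.end
        ]
        if len(hits) != 1:
            raise ValueError(
                f"transcript {transcript_id!r}: CDS {c.start}-{c.end} does not nest "
                f"in exactly one exon"
            )
        cds_by_exon[hits[0]] = c

    coding_idx = sorted(cds_by_exon)
    if coding_idx != list(range(coding_idx[0], coding_idx[-1] + 1)):
        raise ValueError(f"transcript {transcript_id!r}: non-contiguous coding exons")

    # untranslated leading bases of the first coding exon
    first_exon = exon_feats[coding_idx[0]]
    first_cds = cds_by_exon[coding_idx[0]]
    if strand == "+":
        offset = first_cds.start - first_exon.start
    else:
        offset = first_exon.end - first_cds.end

    exons: list[ExonSpec] = []
    exon_seqs: list[str] = []
    start = 1
    for k, i in enumerate(coding_idx, start=1):
        c = cds_by_exon[i]
        span = c.end - c.start + 1
        exons.append(ExonSpec(index=k, c_start=start, c_end=start + span - 1))
        start += span
        exon_seqs.append(fetch(exon_feats[i]))

    intron_seqs: list[str] = []
    for a, b in zip(coding_idx[:-1], coding_idx[1:]):
        ea, eb = exon_feats[a], exon_feats[b]
        if strand == "+":
            seq = str(genome[ea.seqid][ea.end : eb.start - 1]).upper()
        else:
            seq = _revcomp(str(genome[ea.seqid][eb.end : ea.start - 1]).upper())
        intron_seqs.append(seq)

    model = TranscriptModel(
        id=transcript_id,
        exons=exons,
        cds_start_offset=offset,
        exon_seqs=exon_seqs,
        intron_seqs=intron_seqs,
        strand=strand,
    )
    return model


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
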