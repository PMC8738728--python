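"""RNA- and protein-level HGVS consequences of splice events and SNVs.

Derives r.-codes and p.-codes for exon skipping, intron retention and
single-nucleotide changes on a :class:`~splicevar.transcript.TranscriptModel`:

* in-frame, codon-aligned exon skips become ``p.Xi_Yjdel``;
* in-frame but codon-straddling skips become a deletion-insertion with the
  recomputed junction residue (normalized back to a plain deletion when the
  junction residue matches a flanking reference residue);
* frame-disrupting events are scanned for the first novel stop and written
  ``p.XposYfs*N``, counting the first substituted residue as 1;
* retained introns inserted at a codon boundary whose in-frame translation
  reaches a stop at inserted-codon rank N become ``p.Xi_Xjins*N``;
* consequences of several transcript species from one allele combine into
  the bracketed forms ``r.[a,b]`` / ``p.[a,b]``.

Predicted-only protein consequences are wrapped ``p.(...)``; RNA-confirmed
ones are bare.  Confirmation status is an explicit flag, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .transcript import AA3, TranscriptModel, c_to_codon, translate

__all__ = [
    "ConsequenceKind",
    "Consequence",
    "CombinedCodes",
    "skip_to_rcode",
    "retention_to_rcode",
    "consequence_of_skip",
    "consequence_of_retention",
    "consequence_of_snv",
    "combine_allele_consequences",
]

_STOPS = {"TAA", "TAG", "TGA"}


class ConsequenceKind(str, Enum):
    INFRAME_DEL = "inframe_del"
    INFRAME_DELINS = "inframe_delins"
    FRAMESHIFT = "frameshift"
    STOP_INSERTION = "stop_insertion"
    STOP_GAIN = "stop_gain"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"


@dataclass
class Consequence:
    """One RNA-level change paired with its protein-level effect."""

    r_code: str
    p_code: str
    kind: ConsequenceKind
    first_residue: int
    last_residue: int
    deleted_aa_count: int = 0
    fs_stop_rank: int = 0
    in_frame: bool = False


@dataclass
class CombinedCodes:
    r_code: str
    p_code: str


def _wrap(inner: str, confirmed: bool) -> str:
    return f"p.{inner}" if confirmed else f"p.({inner})"


def _res(aa: str, idx: int) -> str:
    return f"{AA3[aa]}{idx}"


# ---------------------------------------------------------------------------
# r.-codes
# ---------------------------------------------------------------------------

def skip_to_rcode(model: TranscriptModel, exon_index: int) -> str:
    """``r.<start>_<end>del`` for skipping of an internal exon."""
    _require_internal_exon(model, exon_index)
    cs, ce = model.exon_c_range(exon_index)
    return f"r.{cs}_{ce}del"


def retention_to_rcode(model: TranscriptModel, intron_index: int) -> str:
    """``r.<a>_<b>ins<a>+1_<b>-1`` for retention of intron a/b."""
    a, b = model.intron_flanks(intron_index)
    return f"r.{a}_{b}ins{a}+1_{b}-1"


def _require_internal_exon(model: TranscriptModel, exon_index: int) -> None:
    if not 1 <= exon_index <= model.n_exons:
        raise IndexError(
            f"transcript {model.id}: exon index {exon_index} out of range"
        )
    if exon_index in (1, model.n_exons):
        raise ValueError(
            f"transcript {model.id}: exon {exon_index} is terminal; "
            "no skip junction exists"
        )


# ---------------------------------------------------------------------------
# protein-level derivations
# ---------------------------------------------------------------------------

def consequence_of_skip(
    model: TranscriptModel, exon_index: int, confirmed: bool = True
) -> Consequence:
    """Protein consequence of skipping one internal exon."""
    _require_internal_exon(model, exon_index)
    cds = model.cds
    prot = model.protein
    cs, ce = model.exon_c_range(exon_index)
    span = ce - cs + 1
    r_code = skip_to_rcode(model, exon_index)

    if span % 3 != 0:
        k = c_to_codon(cs)[0]
        mutant_local = cds[3 * (k - 1) : cs - 1] + cds[ce:]
        return _frameshift_consequence(r_code, prot, k, mutant_local, confirmed)

    i = c_to_codon(cs)[0]
    j = c_to_codon(ce)[0]
    aligned = (cs - 1) % 3 == 0  # implies ce % 3 == 0 since span % 3 == 0
    if aligned:
        p = _wrap(f"{_res(prot[i - 1], i)}_{_res(prot[j - 1], j)}del", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.INFRAME_DEL,
            first_residue=i, last_residue=j, deleted_aa_count=span // 3,
            in_frame=True,
        )

    # in-frame but codon-straddling: residues i..j collapse to one junction
    # residue built from the flanking partial codons
    prefix = cds[3 * (i - 1) : cs - 1]
    junction_codon = prefix + cds[ce : ce + 3 - len(prefix)]
    z = translate(junction_codon + "TAA")[0] if junction_codon not in _STOPS else "*"
    ref_i, ref_j = prot[i - 1], prot[j - 1]
    if z == "*":
        # junction codon is a stop: the protein truncates at residue i
        p = _wrap(f"{_res(ref_i, i)}*", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.STOP_GAIN,
            first_residue=i, last_residue=i, deleted_aa_count=j - i + 1,
            in_frame=True,
        )
    if z == ref_i:
        p = _wrap(f"{_res(prot[i], i + 1)}_{_res(ref_j, j)}del", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.INFRAME_DEL,
            first_residue=i + 1, last_residue=j, deleted_aa_count=j - i,
            in_frame=True,
        )
    if z == ref_j:
        p = _wrap(f"{_res(ref_i, i)}_{_res(prot[j - 2], j - 1)}del", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.INFRAME_DEL,
            first_residue=i, last_residue=j - 1, deleted_aa_count=j - i,
            in_frame=True,
        )
    p = _wrap(f"{_res(ref_i, i)}_{_res(ref_j, j)}delins{AA3[z]}", confirmed)
    return Consequence(
        r_code=r_code, p_code=p, kind=ConsequenceKind.INFRAME_DELINS,
        first_residue=i, last_residue=j, deleted_aa_count=j - i + 1,
        in_frame=True,
    )


def consequence_of_retention(
    model: TranscriptModel,
    intron_index: int,
    snv: tuple[int, str] | None = None,
    confirmed: bool = True,
) -> Consequence:
    """Protein consequence of retaining one intron.

    ``snv`` optionally applies a coding base exchange carried on the same
    transcript molecule (e.g. a last-exonic-base variant that both changes
    an amino acid and disrupts the donor site); residue *names* still refer
    to the reference protein, per HGVS convention.
    """
    intron = model.intron_seq(intron_index)
    cds = model.cds
    prot = model.protein
    if snv is not None:
        c_pos, alt = snv
        if not 1 <= c_pos <= len(cds):
            raise ValueError(f"SNV position c.{c_pos} outside CDS")
        cds = cds[: c_pos - 1] + alt.upper() + cds[c_pos:]
    r_code = retention_to_rcode(model, intron_index)
    P = model.exons[intron_index - 1].c_end  # insertion point, bases before intron

    if P % 3 == 0:
        i = P // 3
        # scan the retained intron in frame for the first stop codon
        stop_rank = 0
        for t in range(len(intron) // 3):
            if intron[3 * t : 3 * t + 3] in _STOPS:
                stop_rank = t + 1
                break
        if stop_rank:
            p = _wrap(
                f"{_res(prot[i - 1], i)}_{_res(prot[i], i + 1)}ins*{stop_rank}",
                confirmed,
            )
            return Consequence(
                r_code=r_code, p_code=p, kind=ConsequenceKind.STOP_INSERTION,
                first_residue=i, last_residue=i + 1, fs_stop_rank=stop_rank,
                in_frame=len(intron) % 3 == 0,
            )
        if len(intron) % 3 == 0:
            pep = translate(intron + "TAA").rstrip("*")
            p = _wrap(
                f"{_res(prot[i - 1], i)}_{_res(prot[i], i + 1)}ins"
                + "".join(AA3[a] for a in pep),
                confirmed,
            )
            return Consequence(
                r_code=r_code, p_code=p, kind=ConsequenceKind.INFRAME_DELINS,
                first_residue=i, last_residue=i + 1, in_frame=True,
            )
        mutant_local = intron + cds[P:]
        return _frameshift_consequence(r_code, prot, i + 1, mutant_local, confirmed)

    # insertion point mid-codon: always a frameshift from the broken codon
    k = P // 3 + 1
    mutant_local = cds[3 * (k - 1) : P] + intron + cds[P:]
    return _frameshift_consequence(r_code, prot, k, mutant_local, confirmed)


def consequence_of_snv(
    model: TranscriptModel, c_pos: int, alt_base: str, confirmed: bool = False
) -> Consequence:
    """Protein consequence of a coding single-nucleotide change."""
    cds = model.cds
    if not 1 <= c_pos <= len(cds):
        raise ValueError(
            f"transcript {model.id}: c.{c_pos} outside CDS (1..{len(cds)})"
        )
    alt = alt_base.upper()
    if alt not in "ACGT" or len(alt) != 1:
        raise ValueError(f"invalid alternate base {alt_base!r}")
    ref = cds[c_pos - 1]
    k, off = c_to_codon(c_pos)
    codon = cds[3 * (k - 1) : 3 * k]
    new_codon = codon[: off - 1] + alt + codon[off:]
    ref_aa = translate(codon + "TAA")[0] if codon not in _STOPS else "*"
    new_aa = translate(new_codon + "TAA")[0] if new_codon not in _STOPS else "*"
    r_code = f"r.{c_pos}{ref.lower()}>{alt.lower()}"

    if new_aa == ref_aa:
        p = "p.=" if confirmed else "p.(=)"
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.SYNONYMOUS,
            first_residue=k, last_residue=k, in_frame=True,
        )
    if ref_aa == "*":
        raise ValueError("stop-loss consequences are not supported")
    if new_aa == "*":
        p = _wrap(f"{_res(ref_aa, k)}*", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.STOP_GAIN,
            first_residue=k, last_residue=k, in_frame=True,
        )
    p = _wrap(f"{_res(ref_aa, k)}{AA3[new_aa]}", confirmed)
    return Consequence(
        r_code=r_code, p_code=p, kind=ConsequenceKind.MISSENSE,
        first_residue=k, last_residue=k, in_frame=True,
    )


def combine_allele_consequences(consequences: list[Consequence]) -> CombinedCodes:
    """Combine transcript species from one allele into bracketed codes.

    A single consequence yields its bare codes; several yield
    ``r.[a,b]`` / ``p.[a,b]`` preserving input order.
    """
    if not consequences:
        raise ValueError("no consequences to combine")
    if len(consequences) == 1:
        c = consequences[0]
        return CombinedCodes(r_code=c.r_code, p_code=c.p_code)
    r_inner = ",".join(c.r_code.removeprefix("r.") for c in consequences)
    p_inner = ",".join(c.p_code.removeprefix("p.") for c in consequences)
    return CombinedCodes(r_code=f"r.[{r_inner}]", p_code=f"p.[{p_inner}]")


# ---------------------------------------------------------------------------
# shared frameshift scanner
# ---------------------------------------------------------------------------

def _frameshift_consequence(
    r_code: str, ref_protein: str, k: int, mutant_local: str, confirmed: bool
) -> Consequence:
    """Name a frameshift from the mutant sequence starting at codon ``k``.

    ``mutant_local`` is the mutant transcript from the first potentially
    affected codon onward.  The first residue differing from the reference
    anchors the fs code; the novel stop is ranked counting that residue
    as 1.  A frame that never reaches a stop is written ``fs*?``.
    """
    mut = translate(mutant_local) if len(mutant_local) >= 3 else ""
    ref_tail = ref_protein[k - 1 :]
    d = 0
    while d < len(mut) and d < len(ref_tail) and mut[d] == ref_tail[d]:
        d += 1
    if d >= len(mut):
        # mutant tail exhausted without difference: degenerate, no novel stop
        pos = k + d
        ref_aa = ref_tail[d] if d < len(ref_tail) else "*"
        p = _wrap(f"{_res(ref_aa, pos)}fs*?", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.FRAMESHIFT,
            first_residue=pos, last_residue=pos, in_frame=False,
        )
    pos = k + d
    ref_aa = ref_tail[d]
    new_aa = mut[d]
    if new_aa == "*":
        p = _wrap(f"{_res(ref_aa, pos)}*", confirmed)
        return Consequence(
            r_code=r_code, p_code=p, kind=ConsequenceKind.FRAMESHIFT,
            first_residue=pos, last_residue=pos, fs_stop_rank=1, in_frame=False,
        )
    stop_idx = mut.find("*", d)
    if stop_idx == -1:
        p = _wrap(f"{_res(ref_aa, pos)}{AA3[new_aa]}fs*?", confirmed)
        rank = 0
    else:
        rank = stop_idx - d + 1
        p = _wrap(f"{_res(ref_aa, pos)}{AA3[new_aa]}fs*{rank}", confirmed)
    return Consequence(
        r_code=r_code, p_code=p, kind=ConsequenceKind.FRAMESHIFT,
        first_residue=pos, last_residue=pos, fs_stop_rank=rank, in_frame=False,
    )
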