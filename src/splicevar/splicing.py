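"""Aberrant-splicing quantification around a heterozygous splice variant.

Given junction-spanning read counts and per-base coverage around one splice
event, this module computes the exon-inclusion ratio (percent spliced in,
PSI), infers the per-allele transcript mixture under an equal-allele-
expression / no-NMD model, quantifies intron retention from coverage ratios
and intron FPKM, flags retention outliers across a cohort, and partitions
allele-tagged reads between correctly spliced and intron-retaining species.

The partition model assumes a heterozygous carrier whose wildtype allele
yields only exon-inclusion transcripts while the variant allele yields only
exon-skipping and intron-retention transcripts, both alleles expressed
equally and no transcript lost to nonsense-mediated decay.  With I the mean
inclusion-junction count and S the skip-junction count, the retention
species is then assigned R = I - S transcripts (clamped at zero), so the
retention fraction of all transcripts is R / (I + S + R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binomtest

import numpy as np

from . import io as svio

__all__ = [
    "JunctionEvidence",
    "TranscriptMixture",
    "AlleleReadPartition",
    "compute_psi",
    "partition_equal_expression",
    "coverage_retention_ratio",
    "intron_fpkm",
    "retention_outlier",
    "allele_read_partition",
    "evidence_from_files",
]


@dataclass
class JunctionEvidence:
    """Junction counts and coverage summaries around one splice event.

    ``inclusion_up`` / ``inclusion_down`` are reads spanning the upstream
    and downstream inclusion junctions of the cassette exon; either may be
    ``None`` when only one junction is measurable.  ``skip`` spans the
    exon-skipping junction.  Coverage fields are mean per-base depths.
    """

    inclusion_up: float | None = None
    inclusion_down: float | None = None
    skip: float = 0.0
    exon_cov: float = math.nan
    intron_cov: float = math.nan
    intron_length: int = 0
    library_size: int = 0

    def __post_init__(self) -> None:
        for name in ("inclusion_up", "inclusion_down", "skip"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def inclusion_mean(self) -> float:
        """Mean of the available inclusion-junction counts."""
        vals = [v for v in (self.inclusion_up, self.inclusion_down) if v is not None]
        if not vals:
            raise ValueError("no inclusion junction count available")
        return float(sum(vals)) / len(vals)

    @property
    def one_sided(self) -> bool:
        return (self.inclusion_up is None) != (self.inclusion_down is None)


@dataclass
class TranscriptMixture:
    """Inferred numbers and fractions of transcript species at one event."""

    inclusion_transcripts: float
    skip_transcripts: float
    retention_transcripts: float
    psi: float
    retention_fraction: float
    skip_fraction: float
    one_sided: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def inclusion_fraction(self) -> float:
        return 1.0 - self.retention_fraction - self.skip_fraction


@dataclass
class AlleleReadPartition:
    """Split of variant-allele-tagged reads into spliced vs retained."""

    alt_reads_total: int
    alt_reads_spliced: int
    alt_reads_retained: int
    retained_fraction_of_alt: float
    binomial_p: float
    verdict: str


def compute_psi(evidence: JunctionEvidence) -> float:
    """Exon-inclusion ratio PSI = I / (I + skip).

    I is the mean of the available inclusion-junction counts — the mean,
    not the sum, because each included transcript contributes to both
    inclusion junctions and summing would double-count it.
    """
    inc = evidence.inclusion_mean
    if inc + evidence.skip == 0:
        raise ValueError("PSI undefined: all junction counts are zero")
    return inc / (inc + evidence.skip)


def partition_equal_expression(
    evidence: JunctionEvidence, nmd_survival: float = 1.0
) -> TranscriptMixture:
    """Infer the transcript mixture under equal allele expression, no NMD.

    ``nmd_survival`` optionally rescales the inferred retention species by
    a survival factor in (0, 1] before fractions are normalized, for
    sensitivity analysis; the default 1.0 is the no-decay model.
    """
    if not 0 < nmd_survival <= 1:
        raise ValueError("nmd_survival must be in (0, 1]")
    inc = evidence.inclusion_mean
    skip = float(evidence.skip)
    if inc + skip == 0:
        raise ValueError("partition undefined: all junction counts are zero")
    warnings_ = []
    if evidence.one_sided:
        warnings_.append("one-sided inclusion evidence: single junction used")
    r = inc - skip
    if r < 0:
        warnings_.append(
            "skip exceeds inclusion: retention clamped to 0 "
            "(inconsistent with equal allele expression)"
        )
        r = 0.0
    r *= nmd_survival
    total = inc + skip + r
    return TranscriptMixture(
        inclusion_transcripts=inc,
        skip_transcripts=skip,
        retention_transcripts=r,
        psi=inc / (inc + skip),
        retention_fraction=r / total,
        skip_fraction=skip / total,
        one_sided=evidence.one_sided,
        warnings=warnings_,
    )


def coverage_retention_ratio(evidence: JunctionEvidence) -> float:
    """Intron-to-exon coverage ratio, an orthogonal retention estimate.

    Works identically whether the two coverage fields are mean per-base
    depths or read counts over equal-length windows; only the ratio enters.
    """
    if not evidence.exon_cov > 0:
        raise ValueError("exon coverage must be > 0 to form a retention ratio")
    if evidence.intron_cov < 0:
        raise ValueError("negative intron coverage")
    return evidence.intron_cov / evidence.exon_cov


def intron_fpkm(count: float, intron_length: int, library_size: int) -> float:
    """Fragments per kilobase of intron per million mapped reads."""
    if intron_length <= 0:
        raise ValueError("intron_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e9 / (intron_length * library_size)


def retention_outlier(fpkm_by_sample: dict[str, float]) -> set[str]:
    """Samples whose intron FPKM exceeds the box-plot fence of the others.

    A sample is an outlier iff its value > Q3 + 1.5*IQR computed on the
    remaining samples (leave-one-out, so a single extreme carrier cannot
    mask itself by inflating the fence).
    """
    if len(fpkm_by_sample) < 3:
        raise ValueError("need at least 3 samples to call outliers")
    out = set()
    for name, value in fpkm_by_sample.items():
        rest = np.array([v for k, v in fpkm_by_sample.items() if k != name], dtype=float)
        q1, q3 = np.percentile(rest, [25, 75])
        if value > q3 + 1.5 * (q3 - q1):
            out.add(name)
    return out


def allele_read_partition(total: int, spliced: int, retained: int) -> AlleleReadPartition:
    """Partition variant-tagged reads into correctly spliced vs retained.

    The two consequences are called "about equally expressed" when the
    retained fraction lies in [1/3, 2/3]; a two-sided binomial test against
    0.5 is reported alongside.
    """
    if spliced < 0 or retained < 0 or total < 0:
        raise ValueError("read counts must be >= 0")
    if spliced + retained > total:
        raise ValueError("spliced + retained exceeds total reads")
    n = spliced + retained
    if n == 0:
        raise ValueError("no reads assigned to either species")
    frac = retained / n
    p = binomtest(retained, n, 0.5).pvalue
    verdict = (
        "about equally expressed"
        if 1 / 3 <= frac <= 2 / 3
        else "unequal expression"
    )
    return AlleleReadPartition(
        alt_reads_total=total,
        alt_reads_spliced=spliced,
        alt_reads_retained=retained,
        retained_fraction_of_alt=frac,
        binomial_p=p,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# file-backed evidence assembly
# ---------------------------------------------------------------------------

def evidence_from_files(sj_path, bedgraph_path, event: dict) -> JunctionEvidence:
    """Assemble JunctionEvidence from an SJ.out.tab file plus bedGraph.

    ``event`` holds the genomic addresses of the junctions and windows,
    1-based closed intervals as emitted by the simulator's layout:
    ``chrom``, ``inclusion_up`` and ``inclusion_down`` (intron intervals),
    ``skip`` (skip-junction intron interval), ``retained_intron_interval``,
    ``reference_exon``, and optionally ``library_size``.
    """
    sj = svio.read_sj_tab(sj_path)
    bg = svio.read_bedgraph(bedgraph_path)
    chrom = event["chrom"]

    def jc(iv):
        return svio.junction_count(sj, chrom, iv[0], iv[1]) if iv else None

    up = jc(event.get("inclusion_up"))
    down = jc(event.get("inclusion_down"))
    skip_iv = event["skip"]
    skip = svio.junction_count(sj, chrom, skip_iv[0], skip_iv[1])

    ri = event["retained_intron_interval"]
    re_ = event["reference_exon"]
    intron_cov = svio.mean_coverage(bg, chrom, ri[0] - 1, ri[1])
    exon_cov = svio.mean_coverage(bg, chrom, re_[0] - 1, re_[1])
    return JunctionEvidence(
        inclusion_up=up,
        inclusion_down=down,
        skip=skip,
        exon_cov=exon_cov,
        intron_cov=intron_cov,
        intron_length=ri[1] - ri[0] + 1,
        library_size=int(event.get("library_size", 0)),
    )
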