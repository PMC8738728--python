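"""Synthetic transcript models and simulated RNA-seq evidence.

The generators emulate the observable structure the analysis assumes: a
heterozygous carrier whose two alleles emit a mixture of normally spliced,
exon-skipping and intron-retaining transcript species, observed as
Poisson-distributed junction-spanning read counts and per-base coverage;
toy coding transcripts with engineered intron sequences whose retained
reading frame hits its first stop codon at a chosen rank; missense-variant
tables with per-domain score distributions; and residue coordinate sets
with an optional planted spatial cluster.

All generators are pure functions of (config, seed) and always return the
ground truth alongside the simulated observations, so downstream
estimators can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as svio
from .domains import DomainMap, ResidueCoordinates, assign_domain
from .splicing import JunctionEvidence
from .transcript import ExonSpec, TranscriptModel

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "make_toy_transcript",
    "make_pnkp_like_model",
    "simulate_junction_evidence",
    "simulate_missense_table",
    "simulate_structure",
    "write_simulated_dataset",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOPS]
)


@dataclass
class SimulationConfig:
    """Conditions of one simulated splice-variant experiment.

    ``mixture`` maps each allele name to a dict of species proportions;
    species are ``"normal"``, ``"skip:<exon>"`` or ``"retention:<intron>"``
    and each allele's proportions must sum to 1.  ``engineered_stop``
    forces the first in-frame stop of a retained intron at a chosen
    inserted-codon rank; a list of (intron, rank) pairs is accepted.
    """

    exon_lengths: list[int] = field(default_factory=lambda: [90, 90, 90, 90])
    intron_lengths: list[int] = field(default_factory=lambda: [90, 90, 90])
    engineered_stop: tuple[int, int] | list[tuple[int, int]] | None = None
    mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"wt": {"normal": 1.0}, "var": {"normal": 1.0}}
    )
    depth: float = 100.0
    coverage_depth: float = 100.0
    library_size: int = 10_000_000
    seed: int = 0
    planted_codons: dict[int, str] = field(default_factory=dict)
    transcript_id: str = "TOY1"
    overdispersion: float = 0.0  # hook; 0 = pure Poisson

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly n_exons - 1 intron lengths")
        if self.depth <= 0 or self.coverage_depth <= 0:
            raise ValueError("depth and coverage_depth must be > 0")
        for allele, props in self.mixture.items():
            s = sum(props.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"allele {allele!r}: proportions sum to {s}, not 1")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def engineered_stops(self) -> list[tuple[int, int]]:
        if self.engineered_stop is None:
            return []
        if isinstance(self.engineered_stop, tuple):
            return [self.engineered_stop]
        return list(self.engineered_stop)


@dataclass
class SimTruth:
    """Ground-truth transcript-species fractions behind simulated counts."""

    psi: float
    retention_fraction: float
    skip_fraction: float
    normal_fraction: float
    cassette_exon: int | None
    retained_intron: int | None


# ---------------------------------------------------------------------------
# toy transcripts
# ---------------------------------------------------------------------------

def make_toy_transcript(config: SimulationConfig) -> TranscriptModel:
    """Deterministic toy coding transcript for a given config and seed.

    The coding sequence starts with ATG, ends with a stop, and contains no
    internal in-frame stop.  When an engineered stop (j, r) is requested,
    the reading frame of retained intron j reaches its first stop exactly
    at inserted-codon rank r.
    """
    rng = np.random.default_rng(config.seed)
    lengths = list(config.exon_lengths)
    total = sum(lengths)
    if total % 3 != 0:
        raise ValueError(f"total coding length {total} is not a multiple of 3")
    n_codons = total // 3
    if n_codons < 3:
        raise ValueError("coding sequence too short")
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=n_codons - 2)) + ["TAA"]
    for idx, triplet in config.planted_codons.items():
        if not 1 < idx < n_codons:
            raise ValueError(f"planted codon {idx} out of range or terminal")
        if triplet in _STOPS:
            raise ValueError(f"planted codon {idx} is a stop codon")
        codons[idx - 1] = triplet
    cds = "".join(codons)

    exon_seqs = []
    pos = 0
    exons = []
    start = 1
    for k, length in enumerate(lengths, start=1):
        exon_seqs.append(cds[pos : pos + length])
        exons.append(ExonSpec(index=k, c_start=start, c_end=start + length - 1))
        pos += length
        start += length

    engineered = dict(config.engineered_stops)
    cum = np.cumsum(lengths)
    intron_seqs = []
    for j, ilen in enumerate(config.intron_lengths, start=1):
        if j in engineered:
            intron_seqs.append(
                _engineer_intron(ilen, engineered[j], int(cum[j - 1]), cds, rng)
            )
        else:
            intron_seqs.append(_random_intron(ilen, rng))
    return TranscriptModel(
        id=config.transcript_id, exons=exons,
        exon_seqs=exon_seqs, intron_seqs=intron_seqs,
    )


def _random_intron(length: int, rng) -> str:
    if length < 4:
        raise ValueError("intron length must be >= 4")
    body = "".join(rng.choice(_BASES, size=length - 4))
    return "GT" + body + "AG"


def _engineer_intron(length: int, rank: int, insertion_point: int, cds: str, rng) -> str:
    """Intron whose retained reading frame first stops at codon rank ``rank``.

    ``insertion_point`` is the c.-position of the last exonic base before
    the intron; its phase decides whether inserted codons read directly
    from the intron (codon-aligned) or complete a broken exonic codon
    first (frameshift).
    """
    if rank < 1:
        raise ValueError("stop rank must be >= 1")
    phase = insertion_point % 3
    if phase == 0:
        if rank < 2:
            raise ValueError(
                "codon-aligned engineered stop needs rank >= 2 "
                "(inserted codon 1 starts with the GT donor motif)"
            )
        stop_at = 3 * (rank - 1)
        needed = stop_at + 3
        if length < needed:
            raise ValueError(
                f"intron of {length} nt too short for a stop at inserted "
                f"codon {rank} (needs {needed} nt)"
            )
        first = "GT" + str(rng.choice(_BASES))
        middle = "".join(rng.choice(_NONSTOP_CODONS, size=rank - 2))
        seq = first + middle + "TAA"
    else:
        lead = 3 - phase
        if rank < 2:
            raise ValueError("frameshift engineered stop needs rank >= 2")
        stop_at = lead + 3 * (rank - 2)
        needed = stop_at + 3
        if length < needed:
            raise ValueError(
                f"intron of {length} nt too short for a stop at codon rank "
                f"{rank} (needs {needed} nt)"
            )
        exon_tail = cds[insertion_point - phase : insertion_point]
        head = ("GT" + "".join(rng.choice(_BASES, size=lead)))[:lead]
        if exon_tail + head in _STOPS:
            head = "C" + head[1:]
        middle = "".join(rng.choice(_NONSTOP_CODONS, size=rank - 2))
        seq = head + middle + "TAA"
    pad = length - len(seq)
    if pad >= 2:
        seq += "".join(rng.choice(_BASES, size=pad - 2)) + "AG"
    else:
        seq += "".join(rng.choice(_BASES, size=pad))
    return seq


# PNKP-like worked-example layout: exon 2 ends at c.151, exon 4 spans
# c.199..498 (300 nt), exon 10 ends at c.936, exon 11 spans c.937..1029
# (93 nt); CDS is 1566 nt (521 residues + stop).
_PNKP_EXON_LENGTHS = [106, 45, 47, 300, 73, 73, 73, 73, 73, 73, 93, 537]
_PNKP_INTRON_LENGTHS = [90, 210, 88, 92, 90, 90, 90, 90, 90, 120, 90]
_PNKP_PLANTED = {
    50: "CAG",   # Gln50
    51: "GTG",   # Val51 (c.151 G is its first base)
    55: "GCT",   # Ala55
    66: "CAG",   # Gln66
    67: "CTG",   # Leu67 (first residue of exon 4)
    101: "CCG",  # Pro101 (c.302 C is its second base)
    104: "CTG",  # Leu104 (c.311 T is its second base)
    166: "AAG",  # Lys166 (last residue of exon 4; c.498 G third base)
    312: "CTG",  # Leu312 (last residue of exon 10)
    313: "TTT",  # Phe313 (first residue of exon 11)
    343: "CCG",  # Pro343 (last residue of exon 11)
}


def make_pnkp_like_model(seed: int = 0) -> TranscriptModel:
    """Toy transcript mirroring the clinically characterized exon layout.

    Residue identities at the positions entering the worked examples are
    planted (Val51, Leu67, Pro101, Leu104, Lys166, Leu312, Phe313, Pro343);
    retained intron 10 reaches its first in-frame stop at inserted codon 18
    and retained intron 2 frameshifts to a stop at codon rank 68.  All
    other sequence content is random given the seed.
    """
    config = SimulationConfig(
        exon_lengths=list(_PNKP_EXON_LENGTHS),
        intron_lengths=list(_PNKP_INTRON_LENGTHS),
        engineered_stop=[(2, 68), (10, 18)],
        planted_codons=dict(_PNKP_PLANTED),
        seed=seed,
        transcript_id="PNKP_TOY",
    )
    return make_toy_transcript(config)


# ---------------------------------------------------------------------------
# junction / coverage evidence
# ---------------------------------------------------------------------------

def _species_fractions(config: SimulationConfig):
    """Overall species fractions (alleles weighted equally)."""
    n_alleles = len(config.mixture)
    normal = skip = ret = 0.0
    cassette = retained = None
    for props in config.mixture.values():
        for species, p in props.items():
            w = p / n_alleles
            if species == "normal":
                normal += w
            elif species.startswith("skip:"):
                skip += w
                cassette = int(species.split(":")[1])
            elif species.startswith("retention:"):
                ret += w
                retained = int(species.split(":")[1])
            else:
                raise ValueError(f"unknown species {species!r}")
    return normal, skip, ret, cassette, retained


def simulate_junction_evidence(
    model: TranscriptModel, config: SimulationConfig
) -> tuple[JunctionEvidence, SimTruth]:
    """Simulate junction counts and coverage for one splice event.

    Junction-spanning reads arise only from fully spliced species:
    inclusion counts are Poisson(depth x normal fraction) at both flanking
    junctions, skip counts Poisson(depth x skip fraction).  Intronic
    coverage is proportional to the retention fraction, exonic coverage to
    all transcripts.
    """
    normal, skip_f, ret_f, cassette, retained = _species_fractions(config)
    if cassette is not None and not 1 < cassette < model.n_exons:
        raise ValueError(f"cassette exon {cassette} is terminal or out of range")
    if retained is not None and not 1 <= retained <= model.n_introns:
        raise ValueError(f"retained intron {retained} out of range")
    rng = np.random.default_rng(config.seed)
    inc_up = int(rng.poisson(config.depth * normal))
    inc_down = int(rng.poisson(config.depth * normal))
    skip = int(rng.poisson(config.depth * skip_f))

    intron_len = (
        len(model.intron_seq(retained)) if retained is not None
        and model.intron_seqs is not None
        else config.intron_lengths[(retained or 1) - 1]
    )
    ref_exon = cassette - 1 if cassette else 1
    exon_len = model.exons[ref_exon - 1].span
    intron_cov = rng.poisson(config.coverage_depth * ret_f * intron_len) / intron_len
    exon_cov = rng.poisson(config.coverage_depth * exon_len) / exon_len

    evidence = JunctionEvidence(
        inclusion_up=inc_up, inclusion_down=inc_down, skip=skip,
        exon_cov=exon_cov, intron_cov=intron_cov,
        intron_length=intron_len, library_size=config.library_size,
    )
    psi = normal / (normal + skip_f) if normal + skip_f > 0 else float("nan")
    truth = SimTruth(
        psi=psi, retention_fraction=ret_f, skip_fraction=skip_f,
        normal_fraction=normal, cassette_exon=cassette, retained_intron=retained,
    )
    return evidence, truth


# ---------------------------------------------------------------------------
# missense tables and structures
# ---------------------------------------------------------------------------

def simulate_missense_table(
    n_per_domain: dict[str, int],
    score_means: dict[str, float],
    score_sd: float,
    seed: int,
    domain_map: DomainMap,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Missense-variant table with per-domain normal score distributions.

    Residue positions are uniform within each domain interval; scores are
    drawn Normal(mean_d, sd).  Domains with n = 0 are absent from the
    table.  Returns (table, true means).
    """
    if not n_per_domain:
        raise ValueError("empty domain map")
    intervals = {name: (a, b) for name, a, b in domain_map.regions}
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for name, n in n_per_domain.items():
        if name not in intervals:
            raise ValueError(f"domain {name!r} not in domain map")
        a, b = intervals[name]
        for _ in range(n):
            i += 1
            pos = int(rng.integers(a, b + 1))
            rows.append(
                {
                    "variant_id": f"var{i:03d}",
                    "position": pos,
                    "score": float(rng.normal(score_means[name], score_sd)),
                    "label": "VUS",
                    "homozygous_in_population": False,
                }
            )
    table = pd.DataFrame(rows)
    return table, dict(score_means)


def simulate_structure(
    n_residues: int,
    planted_cluster: tuple | None = None,
    seed: int | None = None,
    sphere_radius: float = 30.0,
) -> tuple[ResidueCoordinates, list[int]]:
    """Residue C-alpha coordinates uniform in a sphere, optional cluster.

    ``planted_cluster`` is (center, radius, member_positions); center may
    be None for a random interior point.  Planted members are placed
    uniformly within ``radius`` of the center.  Returns the coordinates
    and the list of planted member positions (empty if none).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    def uniform_ball(n, radius, center):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1 / 3)
        return center + v * r[:, None]

    pts = uniform_ball(n_residues, sphere_radius, np.zeros(3))
    members: list[int] = []
    if planted_cluster is not None:
        center, radius, member_positions = planted_cluster
        members = [int(p) for p in member_positions]
        bad = [p for p in members if not 1 <= p <= n_residues]
        if bad:
            raise ValueError(
                f"planted members {bad} exceed n_residues={n_residues}"
            )
        if center is None:
            center = uniform_ball(1, max(sphere_radius - radius, 0.0), np.zeros(3))[0]
        center = np.asarray(center, dtype=float)
        pts[[p - 1 for p in members]] = uniform_ball(len(members), radius, center)
    mapping = {i + 1: pts[i] for i in range(n_residues)}
    return ResidueCoordinates(mapping), members


# ---------------------------------------------------------------------------
# dataset writer (everything the pipeline reads, the simulator can write)
# ---------------------------------------------------------------------------

def write_simulated_dataset(
    model: TranscriptModel, config: SimulationConfig, outdir: str | Path
) -> dict:
    """Write a complete file-backed dataset for one simulated experiment.

    Emits GTF + FASTA for the transcript, an SJ.out.tab-style junction
    file, a bedGraph coverage track, and an event description (JSON) whose
    genomic addresses let the quantifier re-assemble the evidence.
    Returns the event dict.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = svio.write_transcript_gtf_fasta(
        model, outdir / "transcript.gtf", outdir / "genome.fa"
    )
    evidence, truth = simulate_junction_evidence(model, config)
    chrom = layout["chrom"]
    exon_iv = layout["exons"]
    intron_iv = layout["introns"]

    k = truth.cassette_exon
    j = truth.retained_intron
    if k is None or j is None:
        raise ValueError("mixture must name a cassette exon and retained intron")
    up_iv = intron_iv[k - 1]
    down_iv = intron_iv[k]
    skip_iv = (intron_iv[k - 1][0], intron_iv[k][1])

    sj = pd.DataFrame(
        [
            [chrom, up_iv[0], up_iv[1], 1, 1, 1, int(evidence.inclusion_up), 0, 50],
            [chrom, down_iv[0], down_iv[1], 1, 1, 1, int(evidence.inclusion_down), 0, 50],
            [chrom, skip_iv[0], skip_iv[1], 1, 1, 0, int(evidence.skip), 0, 50],
        ],
        columns=svio.SJ_COLUMNS,
    )
    svio.write_sj_tab(sj, outdir / "junctions.sj.tab")

    ref_exon_iv = exon_iv[k - 1]
    ret_intron_iv = intron_iv[j]
    bg = pd.DataFrame(
        [
            [chrom, ref_exon_iv[0] - 1, ref_exon_iv[1], evidence.exon_cov],
            [chrom, ret_intron_iv[0] - 1, ret_intron_iv[1], evidence.intron_cov],
        ],
        columns=svio.BEDGRAPH_COLUMNS,
    )
    svio.write_bedgraph(bg, outdir / "coverage.bedgraph")

    event = {
        "chrom": chrom,
        "transcript_id": model.id,
        "cassette_exon": k,
        "retained_intron": j,
        "inclusion_up": list(up_iv),
        "inclusion_down": list(down_iv),
        "skip": list(skip_iv),
        "retained_intron_interval": list(ret_intron_iv),
        "reference_exon": list(ref_exon_iv),
        "library_size": config.library_size,
        "seed": config.seed,
        "truth": {
            "psi": truth.psi,
            "retention_fraction": truth.retention_fraction,
            "skip_fraction": truth.skip_fraction,
        },
    }
    with open(outdir / "event.json", "w") as fh:
        json.dump(event, fh, indent=2)
    return event
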