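"""Readers and writers for the plain-text formats the pipeline exchanges.

Junction counts use the STAR ``SJ.out.tab`` dialect (nine tab-separated
columns, 1-based closed intron coordinates, unique-read count in column 7);
per-base coverage uses bedGraph (0-based half-open).  Everything the
pipeline reads, the simulator can write, so round trips are testable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SJ_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand",
    "motif", "annotated", "n_unique", "n_multi", "max_overhang",
]

BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def read_sj_tab(path: str | Path) -> pd.DataFrame:
    """Read a STAR SJ.out.tab-style junction file.

    Intron coordinates are 1-based and closed (first/last intronic base).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] != len(SJ_COLUMNS):
        raise ValueError(
            f"{path}: expected {len(SJ_COLUMNS)} SJ.out.tab columns, found {df.shape[1]}"
        )
    df.columns = SJ_COLUMNS
    if df.empty:
        raise ValueError(f"{path}: empty junction file")
    for col in ("intron_start", "intron_end", "n_unique"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative values in column {col}")
    if (df["intron_end"] < df["intron_start"]).any():
        raise ValueError(f"{path}: intron_end < intron_start")
    return df


def write_sj_tab(df: pd.DataFrame, path: str | Path) -> None:
    df[SJ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def junction_count(sj: pd.DataFrame, chrom: str, intron_start: int, intron_end: int) -> int:
    """Unique-read count for one junction; 0 when the junction is absent."""
    hit = sj[
        (sj["chrom"] == chrom)
        & (sj["intron_start"] == intron_start)
        & (sj["intron_end"] == intron_end)
    ]
    return int(hit["n_unique"].sum())


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 bedGraph columns, found {df.shape[1]}")
    df.columns = BEDGRAPH_COLUMNS
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: bedGraph interval with end <= start")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def mean_coverage(bg: pd.DataFrame, chrom: str, start0: int, end0: int) -> float:
    """Mean per-base coverage over a 0-based half-open interval.

    Bases not covered by any bedGraph record count as zero.
    """
    if end0 <= start0:
        raise ValueError("interval end must exceed start")
    sub = bg[(bg["chrom"] == chrom) & (bg["end"] > start0) & (bg["start"] < end0)]
    total = 0.0
    for _, row in sub.iterrows():
        overlap = min(row["end"], end0) - max(row["start"], start0)
        total += overlap * row["value"]
    return total / (end0 - start0)


# ---------------------------------------------------------------------------
# transcript model as GTF + FASTA (toy single-locus genome)
# ---------------------------------------------------------------------------

def write_transcript_gtf_fasta(model, gtf_path: str | Path, fasta_path: str | Path,
                               chrom: str | None = None) -> dict:
    """Serialize a sequence-bearing TranscriptModel as a one-contig GTF+FASTA.

    The contig is the exon/intron concatenation in transcript orientation.
    Returns the genomic layout: exon and intron intervals (1-based closed)
    keyed by index, for use when addressing junction/coverage files.
    """
    if model.exon_seqs is None or model.intron_seqs is None:
        raise ValueError("model must carry exon and intron sequences")
    chrom = chrom or f"{model.id}_locus"
    pieces = []
    exon_iv: dict[int, tuple[int, int]] = {}
    intron_iv: dict[int, tuple[int, int]] = {}
    pos = 1
    for k, seq in enumerate(model.exon_seqs, start=1):
        exon_iv[k] = (pos, pos + len(seq) - 1)
        pieces.append(seq)
        pos += len(seq)
        if k <= model.n_introns:
            iseq = model.intron_seqs[k - 1]
            intron_iv[k] = (pos, pos + len(iseq) - 1)
            pieces.append(iseq)
            pos += len(iseq)
    genome = "".join(pieces)

    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")

    attrs = f'gene_id "{model.id}_gene"; transcript_id "{model.id}";'
    with open(gtf_path, "w") as fh:
        for k in range(1, model.n_exons + 1):
            s, e = exon_iv[k]
            fh.write(
                f"{chrom}\tsplicevar\texon\t{s}\t{e}\t.\t+\t.\t{attrs}\n"
            )
            # CDS = coding part of the exon (drop leading 5' UTR of exon 1)
            cs = s + (model.cds_start_offset if k == 1 else 0)
            ce = cs + model.exons[k - 1].span - 1
            fh.write(
                f"{chrom}\tsplicevar\tCDS\t{cs}\t{ce}\t.\t+\t0\t{attrs}\n"
            )
    return {"chrom": chrom, "exons": exon_iv, "introns": intron_iv,
            "genome_length": len(genome)}
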