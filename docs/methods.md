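# Methods

This document defines the models implemented by `splicevar`, their
assumptions and parameters, the scope of the synthetic-data generators, and
numerical conventions. Everything stated here is computed by the code and
exercised by the test suite; no external datasets are required.

## Transcript model and coordinates

A transcript is an ordered list of exons carrying coding sequence, plus
optional intron sequences. All public interfaces use 1-based, closed
HGVS-style coding coordinates (`c.`), where `c.1` is the A of the start
codon; internally, sequences are sliced with 0-based half-open indices.
Exon *k* covers `c.start..c.end` with contiguous ranges across exons.
Codon and within-codon position of `c.n` are `((n−1)//3 + 1, (n−1)%3 + 1)`.

Validation on construction: exon ranges contiguous, coding sequence starts
with ATG, contains an in-frame stop, and matches the declared exon spans.
Models can be built from an explicit config, from a GTF + FASTA pair
(exact `transcript_id` required; minus-strand features are normalized to
the coding strand), or from the synthetic generators below. Translation
uses the standard nuclear code, stops at and includes the first stop
codon, and ignores a trailing partial codon.

## Splice quantification

**PSI.** For a cassette exon with inclusion-junction read counts
\(I_{up}\), \(I_{down}\) and skip-junction count \(S\), the inclusion
estimate is \(I = \mathrm{mean}(I_{up}, I_{down})\) and
\(\mathrm{PSI} = I / (I + S)\). With counts (30, 33, 24):
\(I = 31.5\), PSI \(= 31.5/55.5 = 0.568\). If only one inclusion junction
is measurable the single count is used and the result is flagged
one-sided.

**Equal-allele partition.** For a heterozygous splice variant, assume
(i) both alleles are expressed equally and (ii) no transcript species is
degraded by NMD. The wildtype allele produces the \(I\) normally spliced
transcripts; the variant allele produces the \(S\) exon-skipping plus
\(R\) intron-retaining transcripts. Equal expression gives
\(R = \max(0, I - S)\); negative solutions are clamped to 0 with a
recorded warning. With (30, 33, 24): \(R = 31.5 - 24 = 7.5\) transcripts,
a retention fraction of \(7.5 / (31.5 + 31.5) = 11.9\%\). An optional
`nmd_survival` factor in \((0, 1]\) rescales \(R\) when partial decay of
the PTC-bearing retention species is assumed.

**Coverage ratio.** An orthogonal retention estimate is the ratio of mean
per-base intronic to exonic coverage, e.g. \(11/69 = 15.9\%\). In a
noiseless mixture this equals the retention fraction exactly (verified by
test); with junction counts it provides an independent consistency check.

**Intron FPKM and outliers.** Intron expression across samples is
compared as FPKM \(= c \cdot 10^9 / (L \cdot N)\) for \(c\) intronic
fragments, intron length \(L\), and library size \(N\). A sample is
called a retention outlier when its FPKM exceeds Q3 + 1.5·IQR of the
remaining samples (leave-one-out box-plot fence).

**Allele-specific expression.** Given reads informative for a
heterozygous marker, the variant-allele fraction is tested against 0.5
with an exact binomial test; alleles are reported as "about equally
expressed" when the fraction lies in \([1/3, 2/3]\).

## Consequence annotation

RNA-level codes follow HGVS style: exon skipping of exon *k* spanning
`c.i..j` is `r.i_jdel`; full retention of intron *k* ending at `c.m` is
`r.m_(m+1)insm+1_(m+1)-1` (e.g. `r.936_937ins936+1_937-1`). Skipping a
terminal exon is rejected.

Protein-level codes are derived from the transcript model:

- **In-frame, codon-aligned skip** (span divisible by 3, boundary on a
  codon edge): deletion of span/3 residues, `p.Xi_Yjdel`.
- **In-frame, codon-straddling skip**: the junction codon is translated;
  if it reproduces the flanking reference residue the deletion is
  normalized to a pure `del`; if it is a stop, the consequence is a stop
  gain `p.Xi*`; otherwise a `delins`.
- **Frameshift** (span not divisible by 3): the mutant transcript is
  conceptually rebuilt and translated; the first residue differing from
  the reference anchors `p.XposYfs*N`, where the stop rank *N* counts the
  first substituted residue as 1. If no stop is reached the rank is
  reported as `fs*?`.
- **Intron retention, codon-aligned**: the intron is scanned in frame;
  the first in-frame stop at rank *N* gives `p.Xi_Yjins*N`; a stopless
  intron of length divisible by 3 gives an `ins` of the encoded peptide;
  otherwise a frameshift.
- **Intron retention mid-codon**: a frameshift starting at the broken
  codon. An optional accompanying single-nucleotide change (e.g. a splice
  donor mutation in the last exonic base) is applied before translation,
  producing codes such as `p.Val51Argfs*68`.
- **SNVs**: `p.(=)` (synonymous), `p.(XposY)` (missense), `p.(Xpos*)`
  (stop gain). Predicted consequences are parenthesized; RNA-confirmed
  ones are bare. Stop-loss variants are out of scope and rejected.

Multiple transcript species from one allele combine into bracketed codes:
`p.[Phe313_Pro343del,Leu312_Phe313ins*18]`.

Correctness of the rule-based deriver is established against an
independent oracle in the test suite: the full mutant cDNA is rebuilt and
translated codon by codon (with a hand-written codon table), and the two
paths are compared on 1000 random toy transcripts as well as on every
worked example.

## ACMG evidence combination

Evidence tokens are `PREFIXnumber[_MODIFIER]` with prefixes PVS, PS, PM,
PP (pathogenic) and BA, BS, BP (benign), and modifier dialects
`_SUP`/`_P`, `_MOD`/`_M`, `_STR`/`_S`, `_VS`. A modifier overrides the
prefix's default strength (e.g. `PVS1_STR` acts as strong).

The **point combiner** assigns supporting = 1, moderate = 2, strong = 4,
very strong = 8 (benign evidence negative; BA1 = −8) and sums:
≥ 10 pathogenic, 6–9 likely pathogenic, 0–5 uncertain, −6..−1 likely
benign, ≤ −7 benign. The **rule combiner** implements the classical
combining table over effective strengths; simultaneous satisfaction of a
pathogenic and a benign rule yields Uncertain with a conflict flag. Both
combiners record a rule trace.

## Missense and structural clustering

A **domain map** partitions protein positions into named regions plus
implicit linkers. Per-region variant counts, fractions (summing to 1 over
all regions), and mean scores are tabulated; differences in a per-variant
numeric score (e.g. a precomputed deleteriousness score) across regions
are tested by one-way ANOVA (`scipy.stats.f_oneway`), with degenerate
inputs handled explicitly (all scores equal → F = 0, p = 1; zero
within-group variance with unequal means → F = ∞, p = 0).

The **clustering test** takes mutated residue positions and Cα
coordinates (from a PDB chain via `gemmi`, preferring blank/'A' altlocs
and skipping insertion-coded residues). The observed statistic is the
mean pairwise Cα distance among the mutated residues. The null resamples
the same number of residues uniformly without replacement from all
resolved positions, and

p = (1 + #{null ≤ observed}) / (1 + B)

for B ≥ 99 bootstrap draws (the +1 correction keeps p > 0 and valid).
The test is invariant under rigid motions of the structure and its null
p-values are verified uniform by simulation.

## Synthetic data generators

All generators are pure functions of a configuration and a seed
(`numpy.random.default_rng`) and return their ground truth alongside the
data.

- **Toy transcripts**: exon/intron lengths are specified; coding sequence
  is ATG + uniformly sampled non-stop codons + stop, with optional planted
  codons at chosen positions. Introns are `GT...AG`; an engineered stop
  can be placed so that retention produces a stop at an exact inserted
  rank, for both codon-aligned and phase-shifted insertion points. A
  bundled 12-exon *PNKP*-like layout reproduces the exon-boundary
  geometry used throughout the documentation.
- **Junction/coverage reads**: species fractions follow a declared
  per-allele transcript mixture; junction counts are Poisson with mean
  depth × species fraction, coverage is Poisson per interval. Recovery of
  PSI and retention fraction from simulated data is bounded in the tests
  (mean absolute error < 0.02 / < 0.03 at depth 2000 over 200 replicates).
- **Missense tables**: per-domain variant counts with Gaussian scores at
  specified domain means.
- **Structures**: residues uniform in a sphere (radius 30 Å by default),
  with an optional planted cluster of chosen members inside a small
  sphere; used to calibrate the clustering test's null and power.

## Numerical conventions

- Counts and coverages are floats; PSI and fractions are exact ratios,
  never rounded internally. Reports round only at presentation.
- Random streams are `numpy` Generators seeded explicitly; identical
  configs reproduce byte-identical outputs.
- File formats: STAR `SJ.out.tab` (9 columns, 1-based closed intron
  coordinates, unique-read count in column 7) and bedGraph (0-based
  half-open). Uncovered bases count as zero coverage.

## Limitations

- The partition model assumes exactly two alleles, equal expression, no
  NMD (or a single scalar survival factor), and that skip and retention
  are the only aberrant species; it does not model partial intron
  retention or cryptic splice sites.
- Consequence annotation covers exon skipping, full intron retention, and
  coding SNVs on a single transcript model; multi-exon events, stop-loss,
  and UTR effects are out of scope.
- The ACMG combiners operate on user-supplied evidence codes; they do not
  derive evidence from data.
- The clustering test treats the structure as static and residues as
  exchangeable under the null; it ignores chain breaks and unresolved
  residues beyond excluding them.
- Simulated reads are independent Poisson counts without positional bias,
  mapping error, or overdispersion (an overdispersion hook exists but the
  default is pure Poisson).
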