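# Methods

`neozscan` detects sex-linked genomic regions in a female-heterogametic
(ZW) system by comparing one female (ZW) and one male (ZZ) individual
against a common reference, and infers the structure of neo-sex
chromosomes formed by autosome–sex chromosome fusions.  This note
describes the model behind each stage, the synthetic data generator used
to verify the pipeline offline, the defaults and the numerical choices.

## The detection model

Two per-window signals distinguish sex-linked from autosomal sequence:

* **Coverage.**  Over a region whose W copy has degenerated, the female
  contributes reads from one chromosome copy where the male contributes
  from two.  If a fraction *w* of the W sequence is retained, the expected
  female:male depth ratio is (1 + *w*)/2 — 0.5 for a fully degenerated W,
  1.0 for a recombining (pseudoautosomal) region.  Depths are normalized
  per individual (below), and the statistic is the female-minus-male
  difference of normalized depths (`cov_diff`), so full degeneration sits
  at −0.5 and retention *w* = 0.5 at −0.25.
* **Heterozygosity.**  Recently sex-linked regions retain W sequence that
  has fixed differences from the Z.  Every such site is heterozygous in
  every female and absent in males, so the female percentage of
  heterozygous sites is elevated while the male's stays at background.
  The statistic is the female-minus-male difference in the percentage of
  heterozygous sites among jointly genotyped sites (`het_diff`).

A region with drastically reduced female coverage and no heterozygosity
excess indicates an old, heavily degenerated W (`HIGH_DEGENERATION`); a
region with moderately reduced coverage and clearly elevated female
heterozygosity indicates a younger stratum with substantial W retention
(`LOW_DEGENERATION`).  Autosomes and PARs show no difference in either
metric.

## Window statistics

Windows default to 100 kb, the standard reporting unit for this kind of
scan; tests use 1–50 kb windows on small simulated genomes.

**Depth** is the mean per-base count of alignment records with at most
`mismatch_filter` mismatches (NM); the default filter of 2 suppresses
reads from diverged paralogs and poorly mapped W reads, and 0 /
unfiltered settings are available for robustness checks.  Unmapped,
secondary and duplicate records are always excluded.

**Normalization** divides each individual's window depths by a refined
genome-wide median: the median of windows lying within a factor 0.8 of an
initial plain median.  When depth-shifted (sex-linked) windows are a
small minority — the situation in real genomes — the refinement changes
nothing.  When they approach half the genome (as in the deliberately
sex-chromosome-rich toy genome), the plain median order statistic lands
in the lower tail of the autosomal depth block and would bias every
normalized value upward by roughly one window-noise SD; the refinement
re-centres the constant on the unshifted depth peak.  Normalization is
idempotent and the calibration (−0.5 / −0.25) is exact in expectation.

**Heterozygosity** is computed from a joint two-sample VCF: a site enters
the denominator when both samples carry a genotype call with depth ≥
`min_depth` (default 3); the window value is 100 × het calls / passing
sites, and windows with fewer than `min_sites` (default 20) passing sites
are missing rather than zero.  The joint denominator makes the
female-minus-male difference exactly antisymmetric under sample swap.

## Consensus pass

The reference derives from the male individual, so female reads carry
systematically more mismatches and map less well — a bias in exactly the
direction of the coverage signal.  The consensus pass substitutes, at
each biallelic SNV, the allele with the majority count across the two
samples' genotypes (four alleles total; ties keep the reference; indels
and multiallelic records are skipped so coordinates never shift) and
recomputes alignments against the result.  Statistics reported by the
pipeline default to the consensus (second) pass.  Rebuilding from
consensus-relative genotypes is idempotent: no new substitutions.

## Synteny anchoring

Window statistics are computed on the fragmented study assembly, whose
scaffolds carry no chromosome coordinates.  Pairwise scaffold-to-
chromosome alignments (PAF) against a contiguous related-species assembly
are filtered to a per-base best-hit set (greater alignment length, then
identity, then target name; losers keep their non-overlapped portions,
affine-trimmed), and each scaffold window is lifted through the anchor
covering its midpoint (strand-aware affine map; a window straddling an
anchor break follows its midpoint).  Lifted values are re-binned into
target windows by weighted mean — coverage weighted by source-window
bases, heterozygosity by genotyped sites — so a lifted window equals the
pooled statistic of its sources; with window-aligned anchors the lifted
profile is identical to one computed directly in chromosome space.
Minus-strand lifting uses the base-level reflection `t = t_end − 1 −
(q − q_start)`, which is an involution and keeps all coordinates inside
half-open intervals.

## Region calling

Windows are flagged one-sidedly at one standard deviation from the
genome-wide mean in the sex-linked direction: `cov_low` below mean − SD
of `cov_diff`, `het_high` above mean + SD of `het_diff`.  The mean/SD
deliberately include sex-linked windows (an option excludes called
regions and iterates once).  One-sided 1-SD flagging marks ≈16% of
windows per metric under pure noise, so flags alone are descriptive; a
*region* is a maximal run of flagged windows tolerating up to `max_gap`
(default 2) unflagged windows, retained only when at least `min_run`
(default 10) of its windows are flagged on a *single* metric.

The `min_run`/single-metric rule is the specificity control, chosen by a
cluster argument before measuring: with flag probability p ≈ 0.3 (either
metric) the chance that a noise flag chains to the next within a ≤2-window
gap is 1 − (1−p)³ ≈ 0.64, so a noise cluster must chain ≈18 times to
accumulate 10 same-metric flags — expected well below one false region
per 2,000 autosomal windows, while any genuine region spanning ≥1 Mb at
100 kb windows passes easily.  A run-length threshold of 3, by contrast,
admits tens of false regions per genome at these flag rates.

Chromosome summaries (mean ± SD of both differences) carry a
reliability flag: chromosomes with fewer than `min_windows` (default 10)
windows are summarized but never promoted to candidate status on their
chromosome-level means alone — deviating means on small chromosomes are
expected from sampling noise.

Region classes: `HIGH_DEGENERATION` if mean `cov_diff` ≤ `cov_drastic`
(default −0.3) without majority heterozygosity support;
`LOW_DEGENERATION` if female heterozygosity is elevated (support ≥ 0.5,
mean `het_diff` > 0) with only moderate coverage loss; anything else is
`LOW_DEGENERATION` with a `weak` annotation.

**Diagnostic loci.**  For wet-lab validation, the pipeline lists indel
sites inside called regions where the female is heterozygous for an
insertion and the male homozygous reference — loci where PCR on
additional females yields two bands and on males one — ranked by
insertion length.

## Boundary and fusion inference

On a second, more contiguous assembly, scaffolds anchored to the synteny
genome are classified by how sex-linkage flags distribute along their
length (after a width-3 majority smoothing of the per-window flags, and
ignoring terminal windows shorter than half the window size):

* flags over part of the scaffold with a single internal transition →
  `PAR_BOUNDARY`, the recombination boundary, lifted to target
  coordinates through the covering anchor;
* flags across the whole scaffold with synteny to two different
  sex-linked chromosomes → `FUSION_POINT`;
* flags across the whole scaffold, positioned at the outer range of a
  called region → `PUTATIVE_FUSION_END` (scaffolds end where the
  non-recombining region ends);
* otherwise `NONE` (multiple transitions are annotated `complex`).

Thresholds: fully flagged ≥ 0.9 (`t_full`), unflagged ≤ 0.1 (`t_none`).

The neo-Z model places the ancestral Z (full length, forward) centrally
and attaches each other region-bearing chromosome as a segment running
from its fused edge — the region edge *without* a PAR boundary — through
the contiguous PAR to the chromosome end, oriented so fused ends abut.
Which end of the Z each partner joins is not identifiable from coverage
or heterozygosity data; partners are attached by a fixed convention
(name order, first partner to the high-coordinate end of Z), which
reproduces the published Sylvioidea layout.  A region with no usable
boundary evidence is attached over its called extent with orientation
`?`.  Models render to a canonical string, one segment per chromosome as
`<chrom>_<startMb>–<endMb>(±)` joined by `_–` with one-decimal Mb — e.g.
`8_28.0–7.3(−)_–Z_0.0–72.9(+)_–4A_9.6–0.0(−)` — and round-trip through
the parser.

## The synthetic data generator

The simulator makes every stage verifiable without sequencing data.  It
plants a declarative architecture (`GenomeSpec`) into one female and one
male individual:

* **W degeneration** is segmental deletion plus fixed substitution: within
  a `SEXLINKED` segment the W haplotype is deleted in blocks of 1 kb with
  probability 1 − `w_retention`, and retained W blocks carry fixed Z–W
  differences at `zw_divergence` per bp (heterozygous in the female,
  absent in the male) and occasional W-linked insertions
  (`zw_insertion_rate`, 5–50 bp) as diagnostic-locus candidates.
* **Individual polymorphism**: heterozygous SNPs at `snp_rate` per bp per
  individual (default 10⁻³, a typical bird-autosome heterozygosity),
  assigned to a random haplotype.  These are recorded as heterozygous
  genotypes for their carrier regardless of W retention — a deliberate
  simplification standing in for the genotype-caller noise floor of real
  data, which keeps background heterozygosity equal between the sexes
  even over hemizygous regions (as observed in real scans, where the
  degenerate Z shows near-zero heterozygosity *difference*).  Without it,
  the variants-only denominator would make fully degenerate regions
  scream in `het_diff` for the wrong reason.
* **Reference error sites** (`ref_error_rate`, default 10⁻⁴): sites where
  both individuals are homozygous for an allele the assembly lacks
  (assembly error / allele dropping).  These give the consensus pass real
  work: they are the sites it substitutes.
* **Reads are placed, not aligned**: single-end records of `read_length`
  (150 bp) are placed uniformly on every sequence-producing haplotype at
  `mean_depth` (default 5×) per haplotype; each record's NM is the exact
  count of variant positions where its source haplotype differs from the
  target genome, so mismatch filters and the consensus recount are
  analytic.  Reads crossing deletion or scaffold junctions are split into
  separate records.  A configurable Poisson error rate is off by default.
* **Assemblies** are simulated by cutting the truth chromosomes into
  scaffolds with exponential lengths (realized N50 within 50% of target),
  reverse-complementing a fraction, and recording truth anchors (emitted
  as PAF).  Scaffold breaks are *forced* at declared fusion edges —
  assemblies of fused genomes break at fusion junctions in
  unfused-synteny coordinates — and random cuts are kept a margin
  (250 kb) away from recombination boundaries, which are ordinary
  contiguous sequence in the study species, so the planted truth
  includes boundary-crossing scaffolds.  Real data offer no such
  guarantee; when no scaffold crosses a boundary the pipeline reports the
  orientation as unresolved rather than guessing.

The default toy genome mirrors the *Sylvietta brachyura* architecture at
1/20 scale: a fully degenerate 5 Mb `chrZ`; a 3 Mb `chr4A` with a still-
recombining 1.5 Mb head and a half-retained tail fused to the Z end; a
4 Mb `chr8` with an autosomal 1 Mb head, a half-retained interior
segment fused at its low edge, and a 1 Mb PAR; and an 8 Mb autosome.
The autosome is sized so unaffected windows are a clear majority
(the normalization constant needs an autosomal mode); with the
chromosome-8 analogue's left flank autosomal, the planted neo-Z truth —
`chr8_4.0–1.0(−)_–chrZ_0.0–5.0(+)_–chr4A_3.0–0.0(−)` — is well defined.

**What the generator does not emulate**: sequencing error and base
qualities, GC and mappability bias, repeats and segmental duplications,
alignment ambiguity, population polymorphism shared between the two
individuals, linked insert pairs, and real assembly-graph artefacts.
Passing tests therefore demonstrate that the *inference machinery* is
correct and calibrated under its stated model, not that real libraries
are free of the mapping artefacts the mismatch filters and consensus
pass exist to mitigate.

## Run design and problem sizes

`run_all` reproduces the study design on one simulation: window scan on a
fragmented scanning assembly (N50 24 kb, the short-read-assembly
analogue), two passes (original reference, then consensus; second pass
reported), lift onto the truth chromosomes, region calling, then boundary
inference on a separate contiguous assembly (N50 1.5 Mb, minimum scaffold
300 kb, maximum 2 Mb so a boundary-crossing scaffold always keeps more
than `t_none` of its length on the minority side).  The boundary pass
reuses first-pass alignments: its signals are strong and a second
consensus pass would not change the calls.  A manifest with config hash,
seed and file checksums makes runs byte-reproducible; two runs with the
same config and seed are identical.

Default sizes keep everything desk-scale: the 20 Mb toy genome at 5×
per haplotype is ~2.4 M placed reads and runs end-to-end in ~10 s; the
specificity check uses 50 all-autosome genomes of 20 chromosomes × 100
windows (20 kb windows over 2 Mb chromosomes).  The real study's
coordinates (from ~100 Gb of reads) are not recomputable at this scale;
the pipeline's file-based entry points (BAM/VCF/PAF) are the real-data
interface.

## Known limitations

* Single female/male pair: polymorphic inversions or diverged autosomal
  haplotype blocks in either individual mimic sex linkage (the published
  chromosome-25 candidate failed PCR validation for exactly this reason);
  the caller cannot distinguish these without more individuals.
* Fusion points are inferred, not observed: without scaffolds crossing a
  fusion junction, `PUTATIVE_FUSION_END` plus convention fixes the
  layout; attachment sides of the Z are a stated convention.
* Heterozygosity uses a variants-only joint VCF; absolute levels depend
  on the caller's site discovery, so only female-minus-male differences
  are interpreted.
* Midpoint lifting assigns a window straddling an anchor break entirely
  to one side; at 100 kb windows this moves boundaries by at most one
  window.
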