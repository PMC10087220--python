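# neozscan

Detection of ZW (neo-)sex chromosomes from female/male whole-genome
coverage and heterozygosity scans — with a synthetic ZW genome and read
simulator that makes the entire pipeline verifiable offline.

## The problem

In birds and other female-heterogametic (ZW) systems, fusions between
autosomes and the sex chromosomes create *neo-sex chromosomes*: formerly
autosomal sequence newly linked to the sex-determining locus.  Once
recombination stops between Z and W over such a region, the W copy
degenerates.  With short-read data from just one female (ZW) and one
male (ZZ) individual, two windowed signals expose this process against a
common reference:

* **normalized genome coverage** — over hemizygous (W-lost) sequence the
  female aligns reads from one copy, the male from two, so the
  female-minus-male difference of normalized window depths (`cov_diff`)
  tends to −0.5; with a fraction *w* of the W retained, the expected
  female:male depth ratio is (1 + *w*)/2;
* **percent heterozygous sites** — retained W sequence carries fixed Z–W
  differences, heterozygous in every female and absent in males, so
  recently sex-linked regions elevate the female-minus-male
  heterozygosity difference (`het_diff`).

Drastically reduced female coverage with no heterozygosity excess marks
an old, heavily degenerated W region; moderately reduced coverage with
clearly elevated female heterozygosity marks a younger stratum.
Autosomes and pseudoautosomal regions (PARs) show no difference in either
metric.  `neozscan` computes these statistics in 100 kb windows (two
passes: against the original reference, then against a majority-allele
consensus that equalizes mapping between the sexes), anchors fragmented
study-assembly scaffolds onto a contiguous synteny genome, segments
outlier windows into classified sex-linked regions, locates PAR
boundaries and putative fusion points from boundary-crossing scaffolds,
and assembles the hypothesized neo-Z chromosome model.  It is aimed at
comparative genomicists screening new taxa for sex-chromosome
rearrangements with minimal sequencing (one individual per sex).

See `docs/methods.md` for the full model, parameter defaults and the
simulator's scope.

## Worked example

The built-in toy genome mirrors a neo-Z architecture at 1/20 scale: a
fully degenerate 5 Mb `chrZ`, a 3 Mb `chr4A` whose distal half is
moderately degenerate (W retention 0.5, Z–W divergence 2×10⁻³) and fused
to one Z end, a 4 Mb `chr8` with a moderately degenerate interior
segment fused to the other Z end and flanked by a PAR, and an 8 Mb
autosome.

```python
from neozscan.pipeline import RunConfig, run_all

result = run_all(RunConfig(outdir="toy_run", seed=1))
print(result.tables["chromosome_summary"].round(4).to_string(index=False))
print(result.tables["regions"].round(3).to_string(index=False))
print(result.model.render())
```

prints (seed 1):

```
chrom  n_windows  mean_cov_diff  sd_cov_diff  mean_het_diff  sd_het_diff  reliable
 chrZ         50        -0.4998       0.0170         0.2882       7.6066      True
chr4A         30        -0.1245       0.1323        16.8216      17.6804      True
 chr8         40        -0.1236       0.1365        17.6969      18.8840      True
 chrA         80         0.0031       0.0183        -1.9779       7.9922      True

chrom   start     end  n_windows  support_cov  support_het  mean_cov_diff  mean_het_diff             klass
 chrZ       0 5000000         50          1.0          0.0         -0.500          0.288 HIGH_DEGENERATION
chr4A 1500000 3000000         15          0.0          1.0         -0.255         33.483  LOW_DEGENERATION
 chr8 1000000 3000000         20          0.0          1.0         -0.258         35.595  LOW_DEGENERATION

chr8_4.0–1.0(−)_–chrZ_0.0–5.0(+)_–chr4A_3.0–0.0(−)
```

Reading the output: the ancestral Z sits at `cov_diff` −0.50 with no
heterozygosity excess (heavily degenerated W); both planted translocated
segments are recovered to the exact window with only moderate coverage
loss (≈ −0.25, i.e. half the W retained) but strongly elevated female
heterozygosity (+33 pp), the young-stratum signature; the autosome is
flat in both metrics.  The model string is the recovered neo-Z: chromosome
8's segment (4.0→1.0 Mb, reversed) fused to Z's start, the whole Z, then
chromosome 4A's segment (3.0→0.0 Mb, reversed) at Z's end — exactly the
planted truth.  `toy_run/` also contains the per-window tables, region
and diagnostic-locus BEDs, boundary calls, the consensus report and a
checksummed manifest.

The same stages run from the shell on real files (coordinate-sorted
BAMs, a joint two-sample VCF, PAF alignments to a synteny genome):

```bash
neozscan simulate --outdir sim --seed 1            # or your own BAM/VCF/PAF
neozscan stats --bam-f sim/female.bam --bam-m sim/male.bam \
               --vcf sim/joint.vcf --out windows.tsv --window 100000
neozscan consensus --ref sim/scaffolds.fa --vcf sim/joint.vcf --out consensus.fa
neozscan anchor --paf sim/anchors.paf --stats windows.tsv --out lifted.tsv
neozscan call --stats lifted.tsv --out calls/
neozscan boundaries --stats windows.tsv --paf sim/anchors.paf \
                    --regions calls/regions.bed --out bnd/ --ancestral-z chrZ
```

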