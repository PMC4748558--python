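# Methods

This note records the models, conventions and numerical choices behind
`aneukit`, and what the synthetic tests do and do not establish.

## Coordinates and input conventions

All internal coordinates are 1-based inclusive, matching published
breakpoint and variant tables; only BED export converts to 0-based
half-open. Chromosome names are normalized to the `chr`-prefixed form
on input (`1`, `chr1`, `X`, `chrX` are all accepted), since published
tables mix conventions. Breakpoint coordinates printed in scientific
notation (e.g. `2.32E+08`) are parsed to exact integers and the
affected side is flagged *coarse*: the printed value carries ±0.5 Mb
uncertainty, three orders of magnitude above the clustering window, so
distances computed against it are meaningful only at that precision.

Variant zygosity is `het`, `hom` (one non-reference allele on all
called copies) or `half-called` (one allele not confidently called).
Half-called records are retained by the readers but excluded from
lesser-allele fractions and from het/hom-ratio denominators: in the
BT-474 library statistics the SNV totals exceed het + hom sums, which
identifies half-called sites as a separate category.

## Translocation clustering

A raw call is a pair of breakpoint windows with a two-letter
orientation code (one letter per side, `f`/`r` relative to the
reference). Calls are first canonicalized so side A precedes side B in
karyotype order; swapping sides exchanges the two orientation letters
(each letter stays attached to its breakpoint) without strand
complementation. Whether the original analysis complemented letters on
side normalization is not documented; the packaged full-precision
calls cluster into exactly their published grouping under the
exchange-only rule, which is the evidence we rely on.

Two canonicalized calls are directly linked iff they share the
chromosome pair and orientation and the interval gap between their
windows is ≤ `cluster_window_bp` (default 5000; overlapping windows
have gap 0) on **both** sides. Events are connected components of this
relation (single linkage). This one rule reproduces both
within-library aggregation and between-library matching. Cluster ids
are assigned deterministically by (chromosome pair, minimal side-A
start, minimal side-B start, orientation).

Single linkage cannot distinguish events whose printed coordinates
were rounded to 1 Mb: distinct junctions > 5 kb apart can collapse
onto one printed value. `resolve_coarse_ambiguity` therefore splits a
cluster along its members' recorded event ids exactly when (a) the
cluster mixes distinct recorded ids and (b) at least one member
carries a coarse side; full-precision clusters are never touched. On
the packaged BT-474 table this affects a single pair of recorded
events whose side-B coordinates both print as `1.91E+08` while their
side-A windows sit 2.2 kb apart.

Fusion support: a candidate (two gene loci on different chromosomes)
is supported iff some cluster joins those chromosomes and each
breakpoint span overlaps, or lies within the clustering window of, the
corresponding gene body, under either side assignment. Orientation is
not constrained — gene strand does not restrict which genomic strands
a junction joins.

## LOH from lesser-allele fractions

Per fully-called variant, LAF = min(d_ref, d_alt)/(d_ref + d_alt);
zero-depth sites are missing. Windows of `laf_bin_bp` (default 100 kb)
tile each chromosome from position 1, keeping the final partial
window; the window statistic is the **median** member LAF, robust to
isolated mapping artifacts (the source analyses state only the window
size, not the statistic).

Note a folding bias inherent to the statistic: at a balanced
heterozygote sequenced to depth N, E[min(X, N−X)/N] < 0.5 (≈ 0.46 at
N = 100). The window median of het-dominated windows is therefore
~0.46, not 0.5 — far from the LOH decision boundary, so segmentation
is unaffected, but consumers of raw LAF values should expect it.

LOH segments are maximal runs of windows with LAF ≤
`laf_zero_epsilon` (default 0.0 exactly; 0.02 recommended for noisy
depths) whose genomic extent strictly exceeds `loh_min_length_bp`
(default 10 Mb). Up to `loh_max_gap_windows` (default 5, i.e. 0.5 Mb)
consecutive variant-free windows are bridged inside a run — otherwise
centromeric gaps would split whole-arm LOH — but runs must start and
end on qualifying windows. Segment bounds snap to window bounds, so
planted-truth recovery is expected only to ±1 window per boundary.

Genome-wide summaries report LOH content by base pairs and by
known-variant content. Without a positional variant catalog, a
segment's variant content is scaled from the chromosome total in
proportion to length; a whole-chromosome segment thus receives the
full count. The packaged per-chromosome BT-474 LOH table sums to
674,184,811 bp (22.2 % of 3,036,303,846) and 11,250,332 variants
(20.3 % of 55,470,937); the published total is 11,250,331, a
printed-rounding difference of one.

## Het/hom-ratio simulation

Deterministic mode: transferred = round(het·f), rounded half away from
zero — this reproduces the published diploid-genome scenario exactly
(2,081,141 × 0.222 = 462,013.3 → 462,013). The "by length" and "by
variants" scenarios are the same formula with different fractions.
Ratios are reported at two decimals alongside full precision.

Regional mode draws contiguous non-overlapping regions (exponential
lengths, default mean 30 Mb, truncated to the host chromosome) until
the target coverage is reached, then converts the heterozygous
variants inside. Region anchors may overhang chromosome ends and are
clipped, which makes per-position coverage probability uniform;
without clipping, chromosome ends are systematically under-covered
and the Monte-Carlo mean departs from the closed form by ~1 % on
small genomes. Counts are exact for the drawn regions; seeded runs are
reproducible.

## Coverage normalization

Read starts are counted in 100 kb windows anchored at position 1.
Haploid copy number is `target_ploidy × count / median(nonzero
autosomal counts)` — the median is robust to the amplified tail of an
aneuploid genome, and by construction the median autosomal bin sits at
the target ploidy (4 by default). Whether the original tetraploid
scaling used mean, median or mode is not documented; the median is
this package's choice. GC correction is not applied. Sex chromosomes
are excluded from the baseline.

## Library concordance

Variant identity is (chrom, pos, ref, alt); genotype is deliberately
ignored, because under aneuploidy the same site can legitimately be
called het in one library and hom in another through allele-fraction
sampling noise. Overlap regions are exact set-algebra counts; panel
recall is |calls ∩ panel|/|panel| with the missing entries listed.

## LFR well statistics

For each variant locus, `well_count` counts wells (of 384) whose reads
call the variant or the reference allele; `shared_well_count` counts
wells calling both; `exclusive_well_count` is their difference. The
min/max exclusive counts are taken over the two per-allele exclusive
tallies (wells calling only reference vs. only variant) — the source
descriptions do not define these two fields operationally, and this is
the interpretation adopted here. `Phased_a_b_h` identifiers are parsed
as contig (a, b) and haplotype h ∈ {0, 1}.

Classification: a variant seen in fewer than `min_variant_wells`
(default 2) wells is a polymerase-error suspect — independent wells
amplify independently, so a random polymerase error is confined to a
single well while a true allele recurs across many. A heterozygote
whose shared-well fraction exceeds 0.5 (configurable) is a
mapping-error suspect: reads from two collapsed loci show both alleles
within single wells. Both thresholds are package choices; the source
material states the principles but no numbers. The expectation that
homozygous non-reference variants concentrate their wells in the
shared field is treated as descriptive and is not enforced or tested.

## Synthetic genome generator

The generator's defaults are the study conditions the package is
tested under: three 30 Mb chromosomes (desk scale; any chromosome map
can be supplied, including the packaged GRCh37 table), tetraploid
baseline, 6 copy-number segments of 2–8 Mb with total copies in
{2, 3, 6, 8, 10}, an LOH target fraction of 0.22 placed as blocks
large enough (> 10 Mb where the budget allows) to be recoverable,
het/hom ratio 1.6 outside LOH (the value typical of a diploid
Caucasian genome), one SNV per kb, 100× depth, three libraries, ≤ 2 kb
breakpoint jitter with 100–1000 bp call windows, 30 % per-library
event dropout plus Poisson(3) false events per library, and a 384-well
layout with ~40 kb fragments (60 per well ≈ 10-fold well coverage per
locus) and single-well polymerase errors at 0.005 error loci per true
locus.

LOH blocks are modeled copy-neutral: the surviving haplotype carries
the full baseline copy number, so LOH is visible to the allele-
fraction channel but not the coverage channel, keeping the two signals
separable in tests. Heterozygous variants whose alt allele sits on the
lost haplotype are removed; those on the surviving haplotype become
homozygous. Read depths are Poisson with mean scaled by local total
copy number; alt depths are binomial in the local alt-copy fraction.
All randomness flows from one seed through named substreams, so each
fixture regenerates independently and byte-identically.

What the generator does **not** emulate: GC and mappability bias,
alignment artifacts, multi-allelic sites, gain-driven allelic
imbalance (LAF strictly between 0 and 0.5), subclonal heterogeneity,
and read-level sequence errors (simulation stops at call-level depths
and well observations). Passing the planted-truth tests therefore
shows the estimators are correct under sampling noise at realistic
scales — not that they are robust to every artifact of real
sequencing data.

## Problem sizes and runtime

The test suite simulates genomes of 6–90 Mb and clusters call sets of
tens to hundreds of rows; the full suite runs in well under a minute
on one CPU, and the packaged-data computations in `scripts/
acceptance.py` complete in seconds. The Monte-Carlo/closed-form
agreement check uses 200 seeded runs on a 20 Mb diploid model with a
3 Mb mean region length.

## Known limitations

* The clustering reproduction of published tables depends on the
  table's own recorded ids wherever printed coordinates were rounded
  to 1 Mb; with full-precision input the algorithm needs no such help.
* LOH segmentation cannot distinguish copy-neutral LOH from hemizygous
  deletion; joint interpretation with the coverage profile is left to
  the analyst.
* `segment_loh` assumes windows from a single pass of
  `compute_laf_windows`; overlapping or duplicated windows are not
  detected.
* Plotting is out of scope; all outputs are tables (TSV/BED/VCF).
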