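# Methods

`gcprofiler` re-implements a tumor/normal genomic-profiling protocol for
low-cellularity cancers (the motivating setting is diffuse-type gastric
cancer, where tumor cells are heavily mixed with stroma) as a reusable,
testable pipeline. Every stage runs on plain tabular inputs — windowed
depth tracks, variant call tables, discordant read-pair records, binned
read counts and BED12 gene models — and every stage is exercised against
a synthetic-cohort generator with known ground truth. This note records
the models, parameter choices and numerical decisions.

## Tumor purity from depth-ratio peaks

A sample of purity `P` mixes tumor and diploid stromal cells. In a
region the tumor carries as a heterozygous deletion (one copy, "1N"),
the expected tumor:normal depth ratio is `(P·1 + 2(1−P))/2 = 1 − P/2`
relative to the diploid ("2N") level, giving

    P = 2 · (R2n − R1n) / R2n

where `R2n` and `R1n` are the histogram locations of the diploid and
haploid ratio peaks. The formula is invariant to global rescaling of
either depth track, so no library-size normalization is needed
(ratios are median-normalized for diagnostics only).

Implementation choices:

- **Windows.** 50-kb windows by default; tumor/normal window sets must
  align exactly; windows with normal depth below 10 are dropped (ratio
  blow-up guard). At least 200 surviving ratios are required.
- **Peak finding.** Gaussian KDE evaluated on a 512-point grid, peaks
  by `scipy.signal.find_peaks` with a relative prominence floor of 10%
  of the density maximum. The bandwidth is the full Silverman reference
  rule `0.9·min(σ, IQR/1.34)·n^(−1/5)`; the IQR term matters because
  minor CNV modes (amplifications) inflate σ and an σ-only bandwidth
  shoulder-merges the 1N peak into the 2N peak.
- **Peak→ploidy assignment.** 2N is the global density mode; 1N is the
  highest-density peak strictly below it (ties toward the lower ratio).
- **Low-purity fallback.** Below `P ≈ 0.5` the two peaks are not
  distinct (at `P = 0.25` the 1N level is 0.875 of the 2N level, inside
  the peak width at realistic window noise). The fallback anchors R1n
  on somatic deletion regions: candidates overlapping any blood-sample
  deletion are excluded, candidates whose mean ratio exceeds the 2N
  level are discarded as false positives, and R1n is the mean ratio
  over the survivors. In anchored mode R2n is likewise the *mean* ratio
  over non-deleted territory: the window-ratio distribution is
  right-skewed (E[T/N] > E[T]/E[N]), so mixing a mode-based R2n with a
  mean-based R1n would bias P upward by several points at low purity.
- Estimates are clamped to [0, 1]; with no distinct peaks and no usable
  anchor the result is `undetermined` rather than a guess.

## Somatic SNV/indel filtering

The cascade over paired tumor/blood call tables, in fixed order (the
order only redistributes the per-stage audit counts; the surviving set
is order-independent and tested as such):

1. keep tumor calls with read depth in [5, 200] and call quality ≥ 20;
2. drop calls present in the blood call set (position + alleles);
3. drop calls where the blood pileup shows depth ≥ 3 and alt-allele
   ratio ≥ 0.2 (missing pileup rows count as depth 0 and are logged);
4. keep only uniquely mapped calls;
5. inside ≥90%-identity duplicated regions (supplied as a BED mask),
   keep only calls detected by both WGS and WES;
6. drop calls in user-supplied known-variant sets (dbSNP-style or
   panel-of-normals-style, keyed by position + alleles).

Consequence annotation translates the affected codon on the coding
strand against the reference sequence: synonymous / nonsynonymous /
nonsense (counted within the nonsynonymous class for scoring), splice
site (the 2 intronic bases flanking each internal exon boundary),
frameshift vs in-frame for CDS indels by length mod 3, noncoding
otherwise. The mutation rate is (SNVs + small indels inside the
sufficiently covered CDS mask, min depth 5) per Mb of mask; the
substitution spectrum collapses the 12 raw substitution types onto the
6 pyrimidine-referenced classes (G>A counts as C>T, and so on).

## Poisson driver scoring

The background expected nonsynonymous count per gene is derived from
the cohort-wide nonsynonymous/synonymous ratio and the observed
synonymous count: `rate = (ns/s)·(s / covered bases)`, i.e. simply
`ns / covered bases`, distributed over each gene's efficiently covered
bases (an optional per-gene nonsynonymous-opportunity fraction can
reweight this; by default opportunity is uniform). Significance is the
exact Poisson upper tail `P(X ≥ obs)`; genes with no observed nsSNV are
kept at p = 1 so the multiplicity family stays well defined. The driver
score is `−log10` of the Benjamini–Hochberg-adjusted p-value — an
explicit choice, since published score columns of this form sit
consistently below `−log10` of the raw p, indicating some adjustment;
BH is the standard one and the raw p is reported alongside. Because BH
is a step-up procedure it can tie adjacent scores; ranking is by raw p,
ties by observed count then gene name. Indels and splice-site SNVs are
tabulated in separate columns and excluded from the observed count by
default (a switch folds indels in).

The exact Poisson test is discrete and conservative: at per-gene
expectations far below 1 (the realistic cancer-cohort regime) its
attained level at nominal 0.05 is ~0.01–0.02, and at expectations of
2–10 it averages ~0.035. The null-calibration experiment is therefore
run at a burden giving per-gene expectations of order 2–10 across a
spread of gene lengths — the regime where the nominal level is
informative — while the power experiment (injected +5 nsSNV drivers
must rank in the top 5) runs at sparse, realistic burden.

## Structural-variation signals

Discordant read pairs (mate order normalized) are typed against the
library insert distribution (median, MAD, k = 3): different chromosomes
→ interchromosomal translocation; same strand → inversion; convergent
pairs by span — above median + k·MAD → deletion, below median − k·MAD →
insertion, above a 1-Mb maximum → intrachromosomal translocation.
Divergent (everted) orientation is also typed intrachromosomal
translocation; the evidence signature of large insertions vs everted
duplications is not distinguishable from span alone, and this
convention keeps the five-class tally exhaustive.

Same-class pairs on the same chromosome pair are single-linkage
clustered with a 400-bp join distance on both ends (the same radius
used for SVS equivalence); clusters need **more than three** (≥ 4)
uniquely mapped pairs to become an SVS. Breakpoint intervals span the
supporting read ends; midpoints are used for distances. A tumor SVS is
somatic when no blood SVS (of any type) has both breakpoints within
400 bp (inclusive). Gene breakage is an SVS breakpoint inside a gene's
transcribed span; an optional exon filter first discards SVSs with
neither breakpoint touching an exon (off by default, so intronic
breakpoints are reported per sample; on for cohort-level impaired-gene
tallies). Fusion candidates are interchromosomal SVSs connecting two
distinct genes with **more than ten** (≥ 11) supporting pairs. The
fused transcript keeps the 5′ partner's exons upstream of its
breakpoint and the 3′ partner's downstream; the junction is in frame
when the retained 5′ CDS length and the lost 3′ upstream CDS length
agree modulo 3 (preserving the downstream codon phase), else a
frameshift — verified in tests by codon-walking designed sequences.

## Copy-number segmentation and classification

Binned tumor/normal read counts (1-kb bins) are segmented by a greedy
adjacent-merge minimizing a BIC-style objective: a binomial
log-likelihood data term (tumor reads among tumor+normal per segment)
plus a per-breakpoint penalty λ = 100. This is a transparent
approximation to BIC-seq — same interface (λ, bin size), not the same
segments. Merging is deterministic (most negative cost delta first,
ties leftmost). The binomial data term assumes near-Poisson counts,
which holds at 1-kb bins; at coarse (50-kb) bins overdispersion
inflates the likelihood ratios and produces spurious single-bin
segments, which is why the segmentation track is binned finely rather
than reusing the purity windows.

Segment states: log2 ratio > 0.2 duplicated, < −0.2 deleted under the
WGS convention (strict inequalities — exactly ±0.2 is neutral);
+0.152173 / −0.135797 under the array-CGH convention. Purity is *not*
used to rescale ratios before classification (raw thresholds, as in the
protocol); consequently a heterozygous deletion becomes undetectable
below purity ≈ 0.5, and the state-recovery test asserts precisely this
degradation. Gene-level state requires a non-neutral state covering
≥ 50% of the gene span; larger coverage wins conflicts, exact ties fall
back to neutral.

## Integration

The alteration matrix is the per-(gene, sample) union of categories
{SNV, INDEL, CNV_loss, CNV_gain, SV_breakpoint} from the three upstream
call sets, with the sample universe and DGC/IGC labels carried
explicitly so unaltered samples count in denominators. Mutual
exclusivity partitions samples by presence of two category classes
(e.g. point mutation vs copy loss) and reports the concomitant
fraction. Cohort comparison takes the per-group sets of genes with at
least one qualifying alteration and reports the overlap via
inclusion–exclusion. A bundled reference table of published CDH1
alterations across an 18-sample cohort (14 diffuse-type, 4
intestinal-type) serves as a worked example and regression input for
these operations.

## Synthetic-data generator

The generator emulates, with known ground truth: (1) depth tracks —
negative-binomial read counts per window (dispersion parameter 400,
i.e. ~5% coefficient of variation for 50-kb windows at 30× — real WGS
depth is overdispersed relative to Poisson), with tumor windows scaled
by the admixture multiplier `(π·c + 2(1−π))/2` inside CNV regions;
(2) variant tables — germline variants (default 1000/Mb genome-wide,
of the order of a human genome's heterozygous-site density) present in
both samples at allele fraction ~0.5, and somatic coding variants
(default 2/Mb of CDS, a typical gastrointestinal-cancer exonic rate)
present only in the tumor at purity-diluted allele fraction
`π/(π·c + 2(1−π))`, drawn nonsynonymous vs synonymous at a configured
ns/s ratio (default 2.5, the human null expectation's order) with
genes weighted by CDS length so intensity is uniform per coding base;
10% of somatic coding events are 1–2-bp indels; driver genes receive
configured extra nsSNVs; (3) discordant read pairs — each SV event
emits its supporting pairs with ±150-bp end scatter (germline events in
both samples), plus uniform noise pairs (default 1/Mb). Somatic
variants are placed in coding sequence only: the pipeline's variant
statistics are all CDS-based, and genome-wide passenger SNVs would only
slow the tables down without exercising any additional code path.

All randomness derives from a single seed through named substreams; a
fixed config reproduces byte-identical outputs. What the generator does
*not* emulate: mapping artifacts, GC/mappability depth waves,
subclonal structure, sequencing error in allele counts, germline
indels, and realistic genome sequence composition. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to artifacts real pipelines must also survive.

## Problem sizes in the shipped experiments

The test and acceptance experiments use compact genomes (10–30 Mb, 2
chromosomes, 80–1000 genes) chosen so each experiment pins its
statistic well within its tolerance: the purity grid uses 600 windows
per sample × 8 purities × 20 seeds; mixture-law checks use ≥ 10⁴
1-kb windows; driver calibration pools 200 genes × 100 cohorts and
power uses 1000 genes × 6 samples × 50 cohorts; segmentation tests use
500–10 000 bins. The CLI demo cohort raises the somatic rate to
60/Mb so a handful of samples yields a non-empty synonymous background
for driver scoring.

## Known limitations

- No joint purity/ploidy inference; the purity model assumes the 2N
  peak is the global mode and 1N regions exist. Whole-genome-doubled
  tumors would violate both.
- Indels are taken as called (no realignment); MSI classification is
  out of scope.
- The segmentation approximates BIC-seq's objective, not its exact
  output; λ is comparable in role but not calibrated to it.
- Fusion frame prediction uses gene-model arithmetic only; no
  split-read or transcript evidence.
- The cohort driver model has no per-gene covariates (expression,
  replication timing); it is the ratio-and-coverage background model
  only.
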