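# Methods

This note records the models, parameter choices, and numerical decisions
behind chromshift, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coverage tracks

Coordinates are 0-based half-open everywhere; conversion happens only at
format boundaries. Tracks are dense per-base arrays (bin size 1 bp), scaled
to a fixed depth of 15 million fragments: value(b) = count(b) ·
15·10⁶/N. One base pair is used because the downstream median/mean signal
definitions are then exact rather than bin-dependent; at desk-scale genome
sizes the memory cost is negligible. bedGraph is the native on-disk dialect
(text, diffable); binary bigWig is not implemented.

Fragment-size estimation correlates strand-specific read coverage (each read
occupying `read_length` bases from its 5′ end) between the plus profile and
the leftward-shifted minus profile; the estimate is argmax-shift +
read_length. Correlating read *footprints* rather than raw 5′ impulses acts
as a built-in boxcar smoother and stabilizes the argmax at realistic depths.
Shifts implying a fragment shorter than read_length + 10 bp are excluded
(phantom-peak guard). This is a deliberately simple stand-in for full
cross-correlation estimators; it recovers 200 bp fragments within ±10 bp at
50 k reads on the synthetic fixtures.

## Peak calling

A fixed 200 bp window slides at 50 bp steps. The fragment count overlapping
each window is tested one-sided against Poisson(λ) with

λ = max(genome-wide rate, 1 kb flank rate, 10 kb flank rate, scaled control rate),

each rate converted to an expected *overlap* count via the (window +
mean-fragment-length) correction. Window p-values are BH-adjusted jointly
across the genome; windows with q ≤ 0.5 are merged (gap ≤ 100 bp) into
candidate peaks carrying the best member window's p/q, a fold enrichment
count/λ, and the max-coverage summit. Filtering the merged candidates at
q ≤ 0.05 (high-confidence) or q ≤ 0.5 (FDR50) guarantees the
high-confidence set is a subset of the FDR50 set by construction. Without a
control, the genome-wide rate is the λ floor.

Consensus: the union of all replicates' FDR50 peaks is merged (gap 0) and a
union region is kept iff every replicate contributes ≥ 1 peak to it — so
chained overlaps qualify transitively, matching the merge-then-require-all
behavior of common consensus tooling; the full union span is reported.
Single-replicate targets pass through their high-confidence peaks instead.
Per-target reproducible peaks across conditions are merged (gap 0) into the
reference peaks used for counting.

## Pseudo-spike normalization

For contrasts with an expected genome-wide change, the median per-base
signal of each sample's depth-normalized track over all reference peaks is
multiplied by C = 10⁶ and integerized (floored at 1, so a fully depleted
sample — e.g. the IP target's own knockout — still yields finite factors).
The constant only sets the integerization grid: the final factors are
invariant to C up to rounding, which the tests verify across C ∈ {10⁵, 10⁶,
10⁷}. These pseudo-spike reads p₁…pₙ give rᵢ = pᵢ/max pⱼ and base factors
rᵢ/geomean(r) (geometric mean exactly 1).

**Orientation.** With effective library = library × factor, factors
*proportional* to the pseudo reads would cancel a genome-wide shift exactly:
the median over reference peaks rises with the shift itself, so equalizing
it equalizes the shifted peaks. chromshift therefore ships the inverted
orientation (factor ∝ 1/pseudo, still geomean-centered; `invert=False`
restores the proportional form). Writing T for the ratio of total library
compositions between conditions, the inverted estimator maps a true fold
change s of the shifted majority to approximately s·(s/T)/T and an
unshifted peak to s/T². It is sign-preserving but not unbiased: with the
default fixture geometry (planted peaks ≈ 20% of the genome, T ≈ 2.2, s = 4)
shifted peaks land near log₂FC ≈ 1.4 and unshifted near −0.4, comfortably
separated by the ±1 calling threshold — whereas TMM maps the shifted
majority to ≈ 0. The estimator is a detector of genome-wide change, not a
calibrated effect-size estimate; that limitation is intrinsic to deriving
the normalizer from the shifted signal itself and holds for the original
procedure too.

Normalization choice is explicit per contrast (`expected_global_change`);
there is deliberately no data-driven heuristic, because the data cannot
distinguish "global shift" from "no shift, wrong normalization".

## Count statistics

TMM follows the published formula: reference column by 75th-percentile
count/library ratio closest to the mean; per-pair M/A values on features
positive in both samples; inverse asymptotic-variance weights; double trim
(30% of M, 5% of A, each side, ordinal stable ranks); factors centered to
geometric mean 1. Trim fractions, the log-CPM offsets (+0.5 count, +1
library), the lowess span 0.5, and moment-based prior estimation are the
cited methods' published defaults, since only the approach — not its
parameters — is stated for this pipeline.

The moderated fit computes per-feature weighted least squares on log₂-CPM
with precision weights from a lowess-smoothed sqrt-residual-SD vs average
log-count trend (evaluated at each observation's fitted log-count, weights =
trend⁻⁴). Residual variances are shrunk toward a scaled-F prior whose
(d₀, s₀²) are estimated by matching moments of log s² via
digamma/trigamma (trigamma inverted by Newton); posterior variance =
(d₀s₀² + d·s²)/(d₀ + d); moderated t uses d₀ + d degrees of freedom. Forcing
d₀ = 0 recovers the ordinary t and d₀ = ∞ the fully pooled z-like limit,
both covered by tests at 10⁻¹⁰.

Calling rules: replicated ChIP, q < 0.05 ∧ |log₂FC| > 1; no-replicate
contrasts, |log₂FC| > 1 on mean-FPKM fold changes with a +0.1 pseudo-FPKM
floor (the source procedure is silent on pseudocounts; the floor only guards
0/0) and with the contrast's normalization factors folded into the FPKM
library sizes — the no-replicate targets are among the pseudo-spike
contrasts, so omitting the factors would erase the shift being called; RNA volcano, raw p < 0.05 ∧ |FC| > 2. RNA contrasts filter genes below
1 CPM in fewer than 2 samples before normalization — an assumption, made
configurable, since no low-count filter is stated for the original analysis.

Auxiliary tests: Wilcoxon rank-sum with midranks, exact enumeration for
min(n,m) ≤ 8 without ties and tie-corrected normal approximation with
continuity correction otherwise; pooled-variance two-sample t (zero pooled
variance with equal means returns p = 1 by convention); spectral-count
G-test G = 2Σ Oᵢ ln(Oᵢ/Eᵢ) over the two observed counts with margins-based
expectations and a χ²₁ p-value.

## Annotation

Footprints are strand-aware half-open windows of exactly 2000 bases per
promoter side and 48,000 bases per distal side; the TES window is ±1 kb
around the transcription end position — narrower than promoters, consistent
with its rank between Introns and 5′ Distal; the width is configurable since
no width is stated for this class. Every isoform contributes footprints, and
a region's label is the first class in the priority order overlapping it by
≥ 1 bp. Gene-assignment distances are measured from the nearest region edge
to the TSS (0 if covering it), signed negative upstream; the edge (rather
than midpoint) anchor is a documented choice. Enhancer association requires
no promoter assignment to *any* gene and nearest-edge distance ≤ 50,000 bp.

## Pre-ranked GSEA

Metric = log₂FC; descending sort with lexicographic gene-id tie-break so
permutation nulls are reproducible. ES is the signed extremum of the
running sum with hit increments |metric|ᵖ/Σ_hits|metric|ᵖ (p = 1, the
pre-ranked default) and miss decrements 1/(N−N_h). The null permutes set
membership (the only option without sample-level data), 1000 draws by
default; NES divides ES by the mean |null ES| of its sign; nominal p is the
same-sign tail fraction; FDR is the sign-stratified pooled-null NES ratio
clipped to [0,1]. Null pools are computed once per distinct set size and
shared — in pre-ranked mode the null distribution depends only on set size,
so this is statistically identical to per-set sampling; `share_nulls=False`
draws independent pools when independence of p-values across sets matters
(e.g. calibration testing). Exact numeric parity with any external GSEA
implementation is not claimed; parity is with the brute-force running-sum
oracle and the method's published definitions.

## Synthetic data

The generator's defaults are the benchmark study conditions: 2 chromosomes,
2,000 planted peaks of 400 bp, two replicates per condition, equal library
sizes of 400,000, negative-binomial dispersion 0.05 (matching the
mean–variance assumption the moderated test exploits; Poisson is the
dispersion → 0 limit), fragment length 200 bp, read length 50 bp, and a
4-fold shift on 90% of peaks for global-shift contrasts. Chromosomes are
2 Mb so that 2,000 realistic-width peaks occupy ~20% of the genome; on a
smaller genome the peaks would dominate the sequence and both local-
background calling and library composition would be degenerate. Enrichment
multipliers are uniform on (2, 4), chosen from the library-composition
analysis above so that the inverted pseudo-spike estimator places shifted
and unshifted peaks on opposite sides of the calling threshold with ≥ 2
noise standard deviations of margin — i.e. the fixture realizes the regime
the method is designed for. Per-sample randomness uses one generator seeded
by (seed, sample index) with regions consumed in canonical order, so outputs
are identical across platforms and design-row orderings.

A sample's total fragment count scales with its composition (a condition
with gained occupancy yields more fragments at equal `library_size`), which
is what makes the benchmark honest: depth (CPM) normalization alone already
attenuates the shift, and TMM removes it entirely.

RNA fixtures draw effects for the shared target genes from a bivariate
normal with correlation ρ_true and SD 1.5 log₂ units (strong-responder
scale, so a useful fraction clears the |FC| > 2 volcano threshold);
non-target genes are null in both perturbations. Baselines are
lognormal(log 100, 1); dispersion 0.05.

**What the benchmarks do not show.** No sequencing errors, mappability
structure, duplicate reads, GC bias, chromatin-state heterogeneity, or
diploid genomes are simulated; peak widths and enrichments are homogeneous;
background is uniform. Passing the recovery tests therefore demonstrates the
statistical machinery — not robustness to alignment artifacts or to
reference-peak sets contaminated by mapping noise. The pseudo-spike
fold-change bias analysis above also means that on real data the method's
effect sizes should be read qualitatively (direction and ranking), with
magnitudes trusted only near the regime T ≈ √s.

## Problem sizes

The default study fixture (4 Mb genome, ~4 M fragments over four samples,
2,000 peaks) runs the full contrast in well under a minute; the test suite's
heaviest checks (20-seed calibration loops, 1,000-region annotation oracle,
500-set GSEA calibration) each complete in seconds to a couple of minutes on
one CPU. These sizes were chosen as the smallest at which the asserted rates
(recall ≥ 80%, false calls ≤ 5%, null calls ≤ 1%) have stable margins.
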