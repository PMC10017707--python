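# Methods

This note documents the models, defaults and numerical choices behind
`depscan`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Dependency scoring

The competition assay is modeled as two exponentially growing populations
mixed 50/50 at day 0.  If the test (knockout) and reference populations
grow at `r_t` and `r_r` log2 units/day, the log2 odds of the test fraction
is exactly `(r_t − r_r)·t`.  We therefore estimate the **log2 relative
growth rate** as the OLS slope of `log2(count_test / count_ref)` on days,
with the slope standard error from residuals, and define the **dependency
score** as the slope's negation (higher = the knockout collapses faster =
more dependent).  Only monotone transforms of the score matter downstream,
because the screen is rank-based.

*Zero counts.*  A timepoint where either population reads zero carries no
finite log odds.  We drop such timepoints rather than add pseudocounts —
pseudocounts bias the slope at the small counts where they matter most —
and raise if fewer than two usable timepoints remain.

*PTF score.*  "Highly expressed" is an operational call on a quantitative
expression table: factor `f` is highly expressed in a line iff its value is
nonzero and ≥ `frac` (default 0.25) of the panel maximum for `f`.  The
fraction is exposed because the underlying laboratory calls are
qualitative; the 0–5 score and the Low (0–2) / High (3–5) grouping do not
depend on it strongly in the synthetic panels.

## TMM normalization

`tmm_factors` implements the published trimmed-mean-of-M-values estimator:
per-bin M and A values against a reference sample, bins zero in either
sample excluded, rank-based double trim (30% on M, 5% on A), and a
precision-weighted mean with inverse delta-method binomial variances,
giving `factor = 2^M̄`; factors are rescaled to geometric mean 1.  The
reference is the sample whose upper quartile of depth-scaled counts is the
panel median — deterministic and standard.  The test suite checks the
implementation against an independent direct computation and against
edgeR's `calcNormFactors` (agreement well under 0.02 on planted
composition-bias fixtures).  Normalized counts are
`raw / (library_size · factor) · 1e6`.

Mapping-quality filtering and BAM parsing are out of scope: fragment lists
are assumed pre-filtered; fragments longer than 800 bp are excluded at
binning, and bin widths default to 1,250 bp (TFs) / 10,800 bp
(histones, BRD4).

## The Kendall screen

Master loci are the union-merge of per-sample peaks, with book-ended
intervals joined (merging convention).  Presence ("detected in a sample")
means overlap with that sample's own peak calls, not a count threshold.
The screen filters require presence in ≥ 3 samples, maximal normalized
count ≥ 10 (the removal rule strikes counts `< 10`, so exactly 10
survives), and cross-mark overlap; when one H3K27ac locus overlaps several
BRD4 loci it pairs with the maximal-overlap partner, ties broken to the
leftmost.  τ is the tie-corrected τ-b (normalized counts can tie), and the
±0.3 cutoff is strict, following the stated rule.  Labels: both τ > 0.3 →
YapD_H; both τ < −0.3 → YapD_L; anything else (one mark under the bar, or
discordant signs) → none.

The screen's operating characteristics at the default panel conditions (19 lines,
effect τ 0.6, NB dispersion 0.2) are measured, not assumed: sensitivity
≈ 0.99 and null false-labeling ≈ 0.003 over 200 replicate panels, and the
null discovery rate matches a score-permutation estimate (the observed
fraction is one draw from the permutation distribution; we check it falls
within 2 SD).

*RRHO.*  Both per-locus statistics are ranked descending (ties broken by
index for determinism) and every threshold pair `(i, j)` on a step grid
(default `N/50`, at least 1) is scored by the upper-tail hypergeometric
`P(X ≥ k | N, i, j)` of the top-set overlap `k`; the grid of −log10 p is
returned.  Sweeping thresholds through the whole lists exposes the four
direction quadrants at the grid corners.

*Clustering.*  Heatmap ordering z-scores rows and applies Ward linkage to
Euclidean distances, which reproduces R's `ward.D2` (checked against R's
`hclust` in the tests).  Constant rows cannot be z-scored and are
signaled; the pipeline drops them with a log message before clustering
screen hits.

## Chromatin states and super-enhancers

Annotation overlaps are strict (≥ 1 bp; book-ended peaks do **not** set a
flag) — deliberately different from the merging convention, separating
"what builds a locus" from "what a locus is positive for".  TSS =
H3K4me3+; active = H3K27ac+ and BRD4+.  The `H3K27ac|BRD4−` shorthand in
the source partition is read as "not double-positive", consistent with the
activity definition; the seven-way partition is: p1 (K4+K27+BRD4+Jun+Sox2+),
p2 (same, Jun−), p3 (other K4+), e2 (K4−K27−BRD4−Jun+Sox2+), e3 (…Jun+Sox2−),
e4 (…Jun−Sox2+), e1 (other K4−).

Co-binding categories partition the 16 Jun/Sox2/Sox5/Twist2 masks into:
all-four; Jun+Sox2+ with exactly one of Sox5/Twist2 (the exclusive
"Sox5|Twist2+" reading — a site bound by both falls elsewhere); other
three-way; two-way; single; none.  Printed-style percentages round
half-up to integers.

Super-enhancers follow the ROSE geometry: CREs with gaps ≤ 12.5 kb are
stitched (no TSS-exclusion window, matching default settings); stitched
regions are ranked ascending by total signal; both axes are scaled to the
unit square; the cutoff is the signal of the first region whose discrete
slope exceeds 1, and every region at or above the cutoff is SE.  The
discrete rule is stated for determinism; degenerate inputs (fewer than 3
regions, or an all-equal signal curve) yield no SE, with a warning in the
first case.  Either H3K27ac or BRD4 signal can drive the ranking; the
pipeline uses H3K27ac.

## Footprinting

"Relative to the local background" is implemented as a **ratio** (fold
over the mean of the outermost 50 bp of the window on each side), making
flank height dimensionless and comparable across antibodies of different
depths; a difference would not be.  Flank width defaults to 20 bp per
side; both widths are configurable.  Relative depth = (flank − core) /
flank is scale-invariant and equals the planted protection fraction in
expectation under the generator's rate model.

Bound/unbound calls use a two-component Gaussian mixture on per-site
footprint depths (posterior > 0.5 for the higher-mean component), with a
fixed random state for determinism.  This replaces an external
framework's internal threshold; only behavioral equivalence on planted
data is claimed (≥ 95% accuracy at protection 0 vs 0.8).  Degenerate
cases — constant scores, or component means closer than 5% of the pooled
spread — call everything unbound with a warning.

The k-mer bias expectation is a deliberately simplified stand-in for full
hexamer regression models: expected signal per position is the global mean
observed signal of that position's centered k-mer, rescaled to preserve
total signal; correction divides observed by expected.  It flattens a
planted hot k-mer but does not model dinucleotide interactions or
strand-specific offsets.

## The synthetic panel

Defaults are the emulated study conditions: 19 lines, dependency scores
uniform on [−0.2, 1.5] log2/day, competition assays at days
0/3/7/10/14 with 10,000 FACS-analyzed cells, and negative-binomial tag
counts with variance `μ(1 + φμ)` (Poisson at φ = 0).

*Planted screen effects.*  A planted locus's per-line mean is
`base_mean · 2^(±A(u − ½))` with `u` the dependency rank scaled to [0, 1]
— Kendall τ of mean vs dependency is exactly ±1 before noise.  The
amplitude `A` is calibrated by bisection so the **expected sample τ-b**
between noisy counts and dependency equals the configured `effect_tau`,
using exact NB pairwise order probabilities (`P(X_t > X_s)` via pmf/sf
products) with an expected-ties correction.  `effect_tau = 1` with
dispersion 0 is emitted noiselessly (the perfectly rank-ordered limit);
targets that saturate the amplitude ceiling (A = 6, a 64-fold swing)
return the ceiling.  Planted loci share a base mean of 50 so one
calibration serves the panel; null loci get per-locus lognormal means
(median 30) constant across lines, hence exchangeable.  The default
detection threshold equals the null median, so null loci are detected in
roughly half the samples.

*State structure.*  One synthetic contig `chrS`; inter-locus gaps are
drawn from 13–30 kb so nothing stitches by accident, except planted
SE clusters: runs of 5 consecutive active CREs spaced 2 kb apart with
~100× enhancer signal, so the tangent rule recovers exactly the planted
clusters.  TF masks are drawn category-first with co-binding enriched at
active loci, and Yap binding probability increases with the number of
co-bound TFs.  A locus negative for everything gets a lone BRD4 call,
because master loci are by construction recognized by ≥ 1 antibody.

*What it does not emulate.*  Read-level artifacts (duplicates, mappability,
GC), sequence-dependent insertion bias, correlated noise between the two
marks, batch structure across lines, and peak-calling uncertainty (peak
boundaries are the true locus boundaries).  Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
stated noise model, not robustness to those real-data pathologies.

## Problem sizes

The replicate counts used throughout (200 panels for screen recovery and
slope recovery, 200 permutations for null calibration, 2,000 sites for
footprint recovery, 100 seeds for the conservation properties) keep every
Monte-Carlo standard error an order of magnitude below the tolerance it
guards while keeping the whole suite under half a minute.
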