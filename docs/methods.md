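# Methods

This note documents the models implemented in `zinchrom`, their
assumptions, the defaults that matter, and the design decisions taken where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and interval arithmetic

All intervals are 0-based half-open `[start, end)` (BED convention), sorted
by `(chrom, start, end)`. Three choices are worth calling out:

* **Merging** coalesces overlapping *and book-ended* intervals: in
  half-open coordinates `[0,10)` + `[10,20)` is contiguous chromatin.
  Merging is a plain union; probabilistic boundary re-estimation (as in
  muMerge-style peak combination) is deliberately not attempted, because
  downstream motif scanning is anchored on region *centers* and a boundary
  shift of a few bp does not move the center materially.
* **Blacklist subtraction** removes any region overlapping a blacklisted
  interval by ≥ 1 bp in its entirety — removal, not trimming — matching the
  usual practice of discarding, not reshaping, artifact-prone peaks.
* **Fractional-overlap intersection** (`intersect_fraction(a, b, f)`)
  retains an a-interval when its overlap with the *union* of b covers at
  least `f` of the a-interval's length. The fraction is measured on the
  a-interval (the ChIP peak in the candidate-selection pipeline). Note this
  is the natural reading of "ChIP peaks that overlapped at least 50%";
  bedtools' `-F` flag measures the fraction of the *B* feature instead. The
  function is symmetric in usage — callers who want the other convention
  can swap the arguments.
* **Promoters** are the 1,000 bp immediately upstream of a TSS
  (strand-aware, clipped at coordinate 0). A region overlapping any
  promoter is labeled `promoter` even if it also overlaps a gene body
  (promoter precedence); otherwise `genic` if it overlaps a gene span;
  otherwise `nongenic`. The three labels partition any region set.

## PWM scanning and exact p-values

Motifs are position probability matrices over A/C/G/T with a 0-order
background π. A pseudocount of 10⁻⁴ is added to each entry (rows then
renormalized) before taking log-odds in bits, so no observed base scores
−∞. The background is estimated from the scanned genome and symmetrized
over complementary bases (A with T, C with G), which makes the null score
distribution strand-invariant so both strands share one p-value table.

Per-column log-odds are discretized to bins of 0.01 bits. The null
distribution of the *binned* window score under π is computed exactly by
dynamic-programming convolution across columns; p-values are its survival
function. Scanned windows are scored with the same binned matrix, so the
reported p-values are exact for the discretized statistic (the test suite
verifies exact agreement with 4^W enumeration, and validity of the
empirical false-positive rate on ≥ 2×10⁶ background positions within a 25%
slack that covers binomial sampling noise at the 10⁻⁴ cutoff).

Scanning covers a ±1,500 bp window around each region center, clipped (not
discarded) at chromosome ends; clipped flanks are padded with N, and any
window containing N can never be a hit. The reverse strand is scanned with
the reverse-complement matrix so forward and reverse hits share genome
coordinates. A region/motif pair's *hit indicator* is binary — at least one
position with p ≤ 10⁻⁵ — with no distance-to-center weighting; the best hit
(lowest p, then smallest |offset|, then + strand) is recorded per pair.

## Differential accessibility

Counts are normalized by median-of-ratios size factors (geometric-mean
reference, factors rescaled to geometric mean 1). The differential test is
a deliberately simple NB Wald-type statistic, not a DESeq2 reimplementation:

* per-region dispersion α by pooled method of moments on normalized counts
  (Var = μ + αμ², floored at 10⁻⁸; no shrinkage toward a mean–dispersion
  trend);
* log₂FC = log₂(μ̂_t/μ̂_c); a pseudocount of 0.5 enters *only* when a group
  mean is zero. Applying it unconditionally would break exact scale
  invariance of the fold change under renormalization (doubling one
  sample's counts and recomputing factors must leave log₂FC unchanged);
* delta-method SE of the log₂ ratio; the Wald statistic is referred to a
  **Student-t with n_c + n_t − 2 degrees of freedom**, not a standard
  normal. With ~5 replicates per group the plug-in dispersion makes the
  statistic approximately t-distributed, and the normal reference is
  anticonservative (empirical type-I ≈ 0.09 at nominal 0.05 in simulation);
  the t reference restores calibration to ≈ 0.05, which the acceptance
  suite checks.

BH adjustment is standard step-up (via statsmodels), with NaN p-values
propagated and excluded from the family size.

**Composition bias.** Median-of-ratios normalization assumes most regions
are unchanged. When a large fraction shifts in one direction (e.g., 30% of
regions up by 1 log₂ unit), the per-sample median lands on a shifted
quantile of the null noise distribution and log₂FC estimates are biased
toward zero by ~0.2–0.3 — a known property of this normalization family,
visible in the synthetic recovery experiments. Consequently (a) effect-size
recovery tests normalize by the generator's recorded true depth factors,
isolating the estimator from the normalization; and (b) the candidate
pipeline computes size factors on the *full* ChIP-peak count matrix rather
than the small post-filter subset, where the planted fraction would be
concentrated. Ranking-based enrichment is unaffected: the bias is a nearly
monotone shift and the E-score is invariant to monotone transforms of the
ranking statistic.

## Enrichment score

Regions are ranked by sign(log₂FC)·(−log₁₀ p), most treatment-increased
first, ties broken by region id. For a motif with hits at 1-based ranks
r₁..r_H among N regions,

E = 1 − 2 · mean_h((r_h − ½)/N) ∈ (−1, 1),

a rescaled Mann–Whitney statistic: positive when motif-bearing regions
concentrate among treatment-opened chromatin, exactly antisymmetric under
ranking reversal, and invariant to monotone transforms of the ranking
statistic. This is a declared stand-in for published TF-enrichment scores
whose exact formula and distance weighting are tool-specific; numerical
parity with any particular tool is a non-goal.

Significance is a two-sided permutation test on hit placements: p =
(1 + #{|E_perm| ≥ |E_obs|}) / (n_perm + 1) with n_perm = 1,000 by default
(+1 correction gives valid finite-sample p-values). When C(N, H) ≤
min(n_perm, 10⁴) the null is enumerated exhaustively and p is the exact
tail fraction. A normal-approximation p (Var(E) ≈ (N−H)/(3NH)) is reported
alongside as a cross-check. All-hit and no-hit motifs are flagged
uninformative (E = 0, p = NaN) and excluded from the BH family, which is
applied across motifs *within* each stratum (all / promoter / nongenic).
Quartile barcodes split the stratum's ranked list into four contiguous
blocks (earlier blocks take the remainder) and count hits per block.

## Zinc quantification

The sensor model is a Hill binding curve: occupancy u = (Zn/K_d)^n, ratio
R = (R_min + R_max·u)/(1 + u). Defaults K_d = 5.3 nM, n = 0.29 describe the
nuclear-localized ZapCV2-class sensor. Calibration is per cell, as in-situ
experiments calibrate: each cell's chelation phase supplies R_min and its
saturation phase R_max; the phase ratio estimator is the median of the last
10 valid frames of the phase (robust to transients; frames with
non-positive corrected donor signal are invalid). Cells with R_max ≤ R_min
or missing calibration phases are excluded with a reason, never silently
dropped.

Inversion: Zn = K_d·u^(1/n) with u = (R − R_min)/(R_max − R). Censoring is
expressed in concentration units: u at or below (floor/K_d)^n reports
`below_range` (floor default 0.001 nM = 1 pM, the sensor's quantification
limit), u at or above (ceiling/K_d)^n (default 5 µM) or R ≥ R_max reports
`above_range`. With the shallow Hill slope (n = 0.29) small ratio errors
translate into large relative concentration errors — ~19% per 0.02 ratio
noise at the low end — which is why plateau medians (√10 noise reduction)
and per-cell medians across ≥ 50 cells are the recommended estimators; the
acceptance suite verifies 10% median recovery across 0.1–100 nM.

The trace generator emits chelation and saturation phases at the exact apo
and saturated limits R_min and R_max. Real calibrations only approach these
limits (a chelator leaves sub-pM zinc; a saturating solution may not fully
saturate a low-n sensor), so real R_min/R_max carry a small bias that the
synthetic roundtrip does not exercise; passing tests demonstrate correct
inversion given correct calibration plateaus, not robustness to incomplete
calibration.

## ChIP-qPCR

Quantities are relative to the undiluted input via a per-target,
per-condition standard curve Ct = intercept + slope·log₁₀(1/dilution) fit
by least squares on ≥ 3 dilution levels (1, 1:10, 1:100, 1:1,000);
amplification efficiency is 10^(−1/slope) − 1, and a non-negative slope
flags the plate. Technical replicates are averaged on the Ct scale;
undetermined Cts are excluded, never imputed.

Percent input scales each quantity to its total eluate and then per unit of
chromatin before the ratio:

%IP = 100 · (q_ip · V_chip_eluate / V_chromatin_for_chip)
          / (q_input · V_input_eluate / V_chromatin_as_input).

This is the standard percent-input arrangement consistent with the listed
volume factors; with the default volumes (220 µl pre-cleared chromatin,
1/10 reserved as input, half the remainder per IP, 200 µl eluates) the
pipeline returns %IP = 100 × bound fraction exactly on noiseless data. The
curve intercept cancels in the ratio, so %IP depends only on Ct
differences. SNR is %IP(+Ab)/%IP(−Ab) with a reference line at 1.5; fold
enrichment divides a treatment's +Ab %IP by the control condition's for the
same target and replicate. Outliers among fold-enrichment values are
flagged by Tukey fences (1.5 × IQR, linear-interpolation quartiles) and
flagged only — values are never dropped.

## Synthetic-data generator

One global seed fans out to fixed per-stage child streams (genome, motifs,
planting, counts, FRET, qPCR, genes, ChIP scenario), so each stage is
independently reproducible and identical configs give byte-identical
files. Every generator records a machine-readable truth table; recovery
tests read truth rather than re-deriving it.

Defaults are the study-scale conditions: a 20 Mb i.i.d. genome at GC 0.45;
2,000 non-overlapping 200 bp regions (uniform over non-overlapping
configurations via the sorted-gap construction); 21 near-consensus PWMs
(0.97/0.01 columns) of width 14, the first of which is planted into 30% of
regions at a random offset and strand; NB counts with control mean 200,
dispersion α = 0.05, 5 replicates per condition, log-normal per-region
baselines (σ = 0.25) and per-sample depth factors (σ = 0.1), and a +1 log₂
accessibility effect for motif-bearing regions in treatment; FRET traces at
resting 0.15 nM and elevated 75 nM with ratio noise 0.02 over 50 cells;
qPCR plates with perfect-doubling chemistry (slope −1/log₁₀2 ≈ −3.3219),
Ct noise 0.15 cycles, six biological × two technical replicates. The
motif width of 14 is chosen so that PWM-sampled sites pass the 10⁻⁵ scan
cutoff with up to two mismatches, putting site-level recovery above 95%;
at width ≤ 12 even one mismatch can push a genuine site past the cutoff.
The qPCR bound fractions are parameterized so the true signal-to-noise of
the low-SNR target (EGR1: 3.24 / 3.52 / 7.91 across control / TPA / ZnCl₂
over a flat −Ab background of 0.002) reproduces the magnitude and ordering
reported for a zinc-responsive p53 target, giving the recovery metrics a
realistic operating point.

What the generator does *not* emulate: read-level data (no fragment-size or
transposase insertion model — counts are drawn directly), GC or mappability
bias, overlapping/nested peaks, correlated motif co-occurrence,
photobleaching or segmentation error in imaging, and qPCR efficiency drift
across dilutions. Passing tests therefore demonstrate the *inferential*
machinery — normalization, testing, ranking, scanning, calibration
inversion, curve fitting — not robustness to those upstream artifacts.

## Numerical choices and degenerate inputs

* Score discretization 0.01 bits bounds the p-value error while keeping the
  DP table ~10⁴ entries; N-containing windows carry a large negative
  sentinel and can never reach any positive cutoff.
* p-values are floored at 10⁻³⁰⁰ before −log₁₀ ranking; ranking ties break
  by region id (deterministic).
* Dispersion method-of-moments can go negative at low sample variance; it
  is floored, never negative.
* Permutation p-values use the +1-corrected estimator except on exhaustively
  enumerable instances, where the exact tail fraction is returned.
* Degenerate enrichment inputs (all-hit/no-hit motifs, empty strata) are
  flagged or raised explicitly; candidate selection returns an explicit
  empty frame when nothing passes the overlap filter.
* The `run-all` manifest hashes every declared output file (SHA-256); rerun
  equality of these hashes is the determinism contract, and the demo
  configuration (300 regions, 6 motifs, 25 cells, 3 qPCR replicates) keeps
  a full double run in the tens of seconds on one CPU.

## Known limitations

* The differential test is intentionally minimal: no dispersion shrinkage
  across regions, no fold-change shrinkage, no outlier refitting, two
  groups only. It is calibrated at the simulated operating point (μ ≈ 200,
  α ≈ 0.05, n = 5 + 5) but will lose power relative to shrinkage-based
  tools at low replicate counts or low counts.
* Median-of-ratios normalization carries the composition bias discussed
  above whenever a large, direction-skewed fraction of regions changes.
* The enrichment score uses binary hits: motif *dosage* (multiple sites per
  window) and distance-to-center weighting are ignored; hooks exist to
  weight hits but no weighting is shipped.
* PWM p-values are exact for the 0-order background; repeat-rich or
  higher-order sequence composition will make them optimistic.
* Zinc estimates assume a single homogeneous sensor pool per nucleus and
  complete calibration plateaus (see above).
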