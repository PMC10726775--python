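# Methods

## Data model

A **template** is the printed A4 sheet: a body silhouette (frontal and
dorsal view side by side on one raster) whose interior is the drawable
region, plus three black fiducial discs outside the silhouette.  A
**pain drawing** is one subject's binary mark raster on that template;
the analysis domain is strictly the silhouette interior, so marks
outside it are clipped (with a warning) wherever a drawing enters the
system.  A **pain profile** for a group is the per-pixel fraction of
drawings marking that pixel.  Rasters are row-major with 0-based
`(row, col)` indices and the origin at the top-left; rectangles are
half-open.  Frontal and dorsal views share one pixel domain and all
statistics treat the sheet as a single raster.

Drawings are serialized as JSON with a per-row run-length encoding of
the mark raster (sorted keys, fixed formatting), so identical drawings
always produce byte-identical files.  Empty drawings are legal but
flagged; they stay in profiles and pixel-count lists (count 0) and are
only excluded where a statistic is undefined (log10 of 0).

## Scan ingestion

1. **Fiducial detection.** Dark connected components (< 60 of 255)
   whose area lies within [0.5, 2]× the expected fiducial area are
   candidates.  The winning triple is the one whose sorted pairwise
   distances match the template triad within 5% relative deviation; the
   triad is deliberately scalene, which also makes the correspondence
   (detected → template order) unambiguous.  Fewer than three
   candidates, no matching triple, or two matching triples are each
   distinct errors.
2. **Registration.** Three non-collinear point pairs determine the
   scan→template affine exactly (one linear solve); the residual on the
   fiducials is zero up to numerics and a residual above 2 px aborts
   extraction with a diagnostic.  Perspective distortion is out of
   scope (flatbed assumption) — the model is affine only.
3. **Mark extraction.** The scan is resampled onto the template grid
   bilinearly and thresholded at the pen/paper intensity midpoint
   (default 142 for ink ≈ 30 and paper 255).  The interpolated
   intensity crosses the midpoint at the true ink boundary, so the
   recovered edge is subpixel-accurate; nearest-neighbor resampling
   with a near-ink threshold was measured to leave half-pixel boundary
   jitter that costs several Dice points on irregular pain blobs
   (min Dice 0.94 vs 0.99 under the default noise model).  The printed
   outline gray (160) stays above threshold; both levels are
   configurable for darker print stock.  Marked pixels are clipped to
   the silhouette and to the exclusion discs of radius 1.5× the
   fiducial radius, and isolated specks of ≤ 2 px (salt-and-pepper
   artifacts) are removed.  Drawing-style rules (no crosses or arrows)
   are not enforced in software; any filled pixel counts.

## Similarity and the permutation test

`RZI(x, y) = Σ min / Σ max` over nonnegative rasters; two all-zero
inputs are defined as identical (RZI 1, with a warning) so the test
remains total on degenerate cohorts.  Pairwise drawing similarities are
computed as intersection/union counts via one matrix product in float64,
which is exact because the counts are integers.

The permutation test pools the drawings, restricts them once to the
union support (pixels marked by nobody contribute zero to both sums, so
this is bit-neutral), and per replicate draws a uniformly random
partition into the original group sizes (independent replicates,
repeats possible).  P-value conventions:

- `lower` (default): `(1 + #{RZI_b ≤ origin}) / (B + 1)`.  Under a
  location/extent difference the true-label profiles are unusually
  *dissimilar*, so the left tail is the coherent difference test; the
  add-one correction counts the observed labeling as one permutation
  and guarantees p > 0.  Validity was checked by simulation: rejection
  rate 0.043 at α = 0.05 over 2000 i.i.d.-raster datasets and 0.052
  over 1000 generator datasets.
- `upper`: mirror image.
- `paper_literal`: `#{RZI_b > origin} / B`, the raw rule found in
  existing field software.  It is small when groups are unusually
  *similar* — the opposite orientation of a difference test — and can
  return exactly 0 on ties; it is kept for fidelity and comparability,
  not as a default, and the package does not guess which behaviour that
  software intended.

`exhaustive_test` enumerates every label assignment once (identity
included, so tail p-values are strictly positive) and refuses cohorts
beyond 200,000 assignments.

Group-level similarity summaries use the distinct off-diagonal pairs of
the three classes (within-A, within-B, between), sample SD (n−1), and
report a within-class as missing when a group has fewer than two
members.  Heatmaps color `log10(max(RZI, 1e-3))`; the floor exists
because fully disjoint pairs (RZI 0) do occur.

## Exact questionnaire tests

For a 2×2 table with fixed margins, the top-left count follows Fisher's
noncentral hypergeometric law with odds-ratio parameter ψ.  Reported
are: the two-sided p-value at ψ = 1 by the point-probability rule
(summing probabilities ≤ that of the observed table, with the customary
1 + 1e-7 tie guard); the conditional MLE solving `E_ψ[X] = x`; and the
exact CI inverting `P(X ≥ x; ψ) = 0.025` / `P(X ≤ x; ψ) = 0.025`.
Root searches use Brent's method with the same bracketing scheme and
default tolerance (machine-ε^¼, reciprocal scale for roots above 1) as
the standard reference implementation of this test, so odds ratios and
CI endpoints printed in the applied literature are reproduced
digit-for-digit; passing a small `tol` instead gives tight inversion
(endpoint tail probabilities within 1e-6 of 0.025), and the package's
invariant tests exercise that mode.  Degenerate margins yield p = 1
with the odds ratio reported as missing; a zero cell yields a boundary
estimate (0 or ∞) with a one-sided interval.

Chi-squared on 2×K tables is Pearson's statistic without continuity
correction (df = K−1); zero-sum columns are dropped with a warning and
expected counts below 5 trigger a validity warning.  The pixel-count
comparison log10-transforms per-drawing counts (zero-count drawings
excluded, with a warning) and applies a two-sided Wilcoxon rank-sum
test — midrank ties, continuity-corrected normal approximation — and a
two-sided two-sample t-test.  Although field reports sometimes label
the former a "signed-rank" test, that test is undefined for two
independent unequal-sized groups; the rank-sum statistic is what the
reported values correspond to, and both the group-A rank sum and the
Mann–Whitney U (what R prints as `W`) are reported.  Odds ratios are
always reported with explicit row/column labels because published
tables are not consistent about orientation.

The bundled survey tables (`paindraw.datasets`) carry the full printed
response counts of a 49-patient body-outline survey; the question-5
table is flagged as internally inconsistent with its originally
reported odds ratio and excluded from validation.

## Synthetic data generator

The generator emulates the study conditions rather than any particular
patient: two A4 templates at 150 dpi (1240×1754 px) with parametric
silhouettes whose shoulders/chest/waist differ between the `female` and
`sexless` variants while the abdominal-to-crotch band is geometrically
identical — matching drawable area in the clinically critical band so
area comparisons cannot be an artifact of outline size.  Cohort
defaults: 24 drawings on the sexless and 26 on the female template;
1–4 pain blobs per drawing; total marked area log-normal with log10
mean 3.3 and SD 0.45 px (the scale of observed log10 pixel-count
distributions at 150 dpi); blob locations drawn from region weights
concentrated on the abdomen (0.45) with lower back (0.20), back (0.15),
legs (0.12) and chest (0.08).  Blobs grow by Eden-style random frontier
accretion until the target area, clipped to the silhouette's reachable
component (capped with a warning if the region is exhausted).  Optional
group-B effects: an area multiplier or different region weights.
Everything is a pure function of (config, seed).

Scan renders place gray outline contours (160), black fiducials and pen
marks (≤ 30) on white paper, apply a random similarity transform about
the page center and return it as ground truth, then add noise.  Default
noise model: rotation ±3°, translation ±10 px, scale ±2%, Gaussian
intensity σ = 8, salt-and-pepper 0.1%, pen-gap dropout 1% of mark
pixels.  What the generator does *not* model: perspective/lens
distortion, paper folds, smudging, colored ink, anatomically realistic
pain shapes, or correlation between neighbouring patients — so passing
round-trip tests demonstrate geometric and intensity robustness, not
clinical realism.

## Problem sizes and numerical choices

Cohort-level simulation checks (type-I calibration, power) run on a
quarter-linear-scale raster (310×438) with per-drawing areas rescaled
by the dimensional rule area ∝ s²(log10 mean 3.3 → 2.1) and every other
default untouched; this preserves the coverage density that drives
overlap behaviour, and full-scale spot checks agree.  Calibration uses
200 no-effect cohorts (n = 10+10, B = 200, α = 0.05); power uses 100
cohorts with fully disjoint region weights (chest vs legs).  Ingestion
fidelity is scored at full scale (50 default-noise renders, Dice
against retained ground truth; zero-noise renders must recover
exactly).  The study-scale replica (24+26, B = 1000) runs in well under
a minute on one CPU and is bit-reproducible from its seed, including
PNG artifacts (Agg backend, fixed metadata).

Ties in the rank-sum test use midranks; SDs are sample SDs; the
permutation-test RNG is NumPy's PCG64 seeded explicitly everywhere.
Degenerate inputs have defined behaviour throughout: empty drawings
(warn, RZI convention 1 on empty pairs), single-member groups (within
stats missing), zero margins (p = 1, OR missing), zero-variance Welch
samples with equal means (t = 0, p = 1).

## Known limitations

- The affine registration cannot absorb perspective or nonrigid page
  distortion; such scans fail the residual gate rather than silently
  degrading.
- The conditional-MLE solver targets 2×2 tables only; stratified
  (2×2×k) designs are out of scope.
- The permutation test compares exactly two groups; multi-group designs
  and covariate adjustment are out of scope.
- Interoperability with any external pain-drawing software's JSON
  format is not claimed; the schema here is self-describing.
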