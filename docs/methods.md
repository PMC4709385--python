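# Methods

## The assay and the score

`bgikit` quantifies early biofilm growth from ordinary photographs of
stained sample coupons. A broad-spectrum biomolecular stain darkens a
coupon wherever biomass sits, so darkness in the photograph carries the
signal. Over a user-chosen rectangular region of interest (ROI, chosen
to exclude coupon edges, mounting holes and markings) the analysis is:

1. **Channel separation.** The RGB photograph is split into red, green
   and blue planes; a grayscale plane serves as an overall average.
   Each plane is scored independently on its own histogram.
2. **Multilevel Otsu thresholding.** N = 10 thresholds partition the
   256-bin intensity histogram into 11 classes by minimising the
   count-weighted sum of within-class intensity variances (the
   multilevel generalisation of Otsu's criterion). Quantised class
   indices stretched over 0–255 give the contrast-enhanced inspection
   image.
3. **Ramp filter.** Per-class pixel counts are weighted linearly:
   weight 0 for the brightest class rising in steps of 1/N to weight 1
   for the darkest. The weighted sum is the filtered histogram area
   A2; the ROI pixel count is A1.
4. **Score.** BGI = 100 · A2 / A1. It is 100 exactly when every pixel
   is in the darkest class and 0 when every pixel is in the brightest,
   equals 100 × the mean darkness weight per pixel, and depends only on
   the histogram (never on pixel arrangement). Unlike binary areal
   coverage it responds to the depth and density of staining, not just
   its extent.

Two comparator metrics are provided: binary Otsu areal coverage
(percentage of pixels in the dark class of a one-threshold split) and
manual-range coverage (percentage of pixels inside an explicit
`[low, high]` intensity range).

### Ramp-weight spacing

Describing 11 groups with weights "0, 1/11, 2/11, …, last = 1" is
arithmetically inconsistent: ten steps of 1/11 from 0 end at 10/11.
This implementation fixes the endpoints that the score's 0/100
definitions force — weight_g = g/N for g = 0..N, so the darkest class
carries exactly 1 — and exposes `ramp_denominator` for anyone wanting
the literal 1/11 spacing (whose top weight is 10/11, so a saturated
coupon then tops out at 100·10/11 ≈ 90.9).

### Threshold conventions and edge cases

* A pixel with intensity `v <= t` joins the class **below** threshold
  `t`. One convention had to be chosen; this one is applied everywhere
  (quantisation, coverage, the DP optimiser) and is asserted by tests.
* The multilevel optimum is found by exact dynamic programming over
  cumulative count / count·intensity / count·intensity² sums —
  guaranteed global optimum for N = 10 in milliseconds, no stochastic
  search. Ties between equally optimal threshold vectors break toward
  the lexicographically smallest vector (verified against exhaustive
  enumeration on reduced histograms).
* Histograms with at most N distinct intensities cannot accommodate N
  variance-reducing thresholds; `multilevel_otsu` raises. For scoring,
  such degenerate channels (blank or fully saturated coupons — red and
  blue channels of heavily fouled coupons do saturate) fall back to the
  direct intensity mapping BGI = 100 · mean(255 − v)/255, which for a
  single uniform intensity v is exactly 100·(255−v)/255 and preserves
  continuity at the extremes (uniform white → 0, uniform black → 100).
* Grayscale conversion defaults to ITU-R BT.601 luma
  (0.299 R + 0.587 G + 0.114 B), the standard camera-pipeline
  convention; `gray_weights="equal"` gives the plain channel mean.
  16-bit sources are divided by 257 so every histogram has 256 bins.

## Cell-density control

The independent control converts the optical density of a suspension of
cells sonicated off a paired coupon:

* cells/mL = 3.9 × 10⁸ × OD₆₀₀ (valid as a rough proportionality for
  0–1 AU; a warning is emitted above 1),
* cells/cm² = cells/mL × suspension volume / (2 × side²) for a
  two-sided square coupon (defaults 15 mL, 2.5 cm).

## Ranking image-analysis methods

Each metric's sample series is compared with areal cell density via a
composite fit: Pearson r times the slope m of an ordinary
least-squares fit, both computed after

* **log₁₀-transforming the control** — cell density spans orders of
  magnitude while image metrics are linear, and the assay's own
  convention plots density on a log axis. Non-positive densities are
  floored one decade below the smallest positive observation. The
  transform is configurable (`control_transform="linear"`).
* **min–max normalising both series to [0, 1]** before the slope fit,
  so "m nearest 1" is meaningful across metrics with different units.

Score = r·m when both factors are positive, else 0. The plain product
alone would be wrong: an anti-correlated metric has r ≈ −1 *and*
m ≈ −1, whose product is +1, yet it is the worst possible fit under the
"both nearest 1" criterion, so either factor being non-positive zeroes
the score. The score is capped at 1.

Replicates are treated as independent paired samples (12 pairs for a
triplicate, four-time-point design); `average_by_time=True` collapses
them to per-time-point means (4 pairs) as a sensitivity option.
Ranking is by descending score with alphabetical tie-break.

## Synthetic coupon generator

`synthetic` renders the kind of photograph the assay consumes, so the
full pipeline is testable without laboratory data. One 500×500 px
coupon is composed of:

* a green-tinted substrate (default RGB 168/186/152) with fine Gaussian
  texture and a periodic weave pattern (amplitude 6), emulating
  green-tinted fiberglass;
* sparse dark specks (0.1 % of pixels, dilated; dust, pores, fibre
  ends) — growth-independent;
* a faint large-scale residual-stain mottle (opacity amplitude 0.18) —
  growth-independent;
* a stained-biofilm layer: 48 Gaussian patches of ~50 px radius summed
  into a smooth field (normalised by its 95th percentile), driving a
  stain opacity 0.15·g + 1.0·g·field^0.6 for growth level g ∈ [0, 1],
  composited **multiplicatively** (substrate × per-channel
  transmission toward the purple-hued stain tint 72/44/90), so the
  channels the stain absorbs most saturate first at high growth;
* additive Gaussian sensor noise (σ = 2 intensity units), clipped and
  rounded to 8 bits.

All randomness comes from one seed, and the random draws do not depend
on the growth level, so the stain opacity is pixelwise nondecreasing in
g at a fixed seed.

The growth-independent substrate features are not decoration; they are
what makes the generator behave like real photographs under
*adaptive* thresholding. Without them a clean coupon is pure sensor
noise, the ten thresholds stretch that noise across all eleven classes,
and the clean coupon scores ≈50 — something never seen on real images,
whose histograms are anchored by specks, weave and residual stain. With
them, a clean coupon scores low (≈35) and BGI rises smoothly with
growth, while binary Otsu reproduces its known failure on stained
coupons: the residual mottle gives clean images ≈30–50 % "coverage"
with large replicate swings, followed by a plateau — coverage saturates
in area while the biofilm keeps deepening.

`generate_growth_series` emulates the paired-coupon design: triplicate
coupons at 0, 48, 72 and 144 h; areal density grows exponentially from
4 × 10⁵ cells/cm² with a 15 h doubling time and lognormal replicate
scatter (σ = 0.25 natural-log units); growth level is log₁₀ density
mapped linearly across 10⁵·⁵–10⁸·⁵ cells/cm², saturating at 1; OD₆₀₀
in the control table is back-computed through the assay geometry so the
conversion arithmetic round-trips. An `stained=False` option compresses
the optical dynamic range to ~6 %, emulating unstained coupons whose
darkening is barely visible.

### What the generator does *not* emulate

Lighting gradients and glare, lens distortion, camera RAW processing,
real biofilm morphology (streamers, rims), between-coupon tint
variation, and the chemistry of differential dye binding. Passing tests
therefore show that the *algorithms* behave as specified on images with
realistic histogram structure — not that the assay will achieve any
particular accuracy on a given laboratory's photographs.

### Expected strict monotonicity, not per-replicate

BGI under image-adaptive thresholds is not strictly monotone in growth
at every step: newly added dark mass re-anchors the classes and can
nudge a single colour channel down a few units over a small growth
increment (observed in ~1 % of fine-grid transitions). Monotonicity
holds per seed across well-separated growth levels (0.2 vs 0.8, every
channel, all seeds tested) and for the seed-averaged score over a fine
grid, which is what the generator's contract ("expected darkness
nondecreasing") promises.

## Problem sizes used in tests

Unit tests use coupons of 160–250 px; the end-to-end ranking study uses
the full default conditions (500×500 px coupons, 4 time points × 3
replicates) replicated over 100 seeds, which completes in a few minutes
on one CPU. The threshold optimiser is validated against exhaustive
enumeration on 500 random 16-level histograms (2 and 3 thresholds) and
against an independent implementation's threshold values on full
256-bin histograms.

## Known limitations

* BGI is a within-image contrast measure: uniform darkening with no
  contrast change is invisible to it (adaptive thresholds shift with
  the histogram). Staining that produces heterogeneous, anchored
  histograms is a prerequisite, as it is for the physical assay.
* The OD-to-cell conversion is a linear approximation valid below 1 AU.
* The manual-range comparator's published coverage figure depends on an
  unpublished threshold choice and is not reproduced here.
* Interactive ROI selection is deliberately unsupported; coordinates
  are explicit for reproducibility.
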