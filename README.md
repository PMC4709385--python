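# bgikit

Quantify early biofilm growth from ordinary photographs of stained
sample coupons.

Early-stage biofouling is soft, patchy and nearly transparent: binary
image thresholding (Otsu's method or a hand-picked range) measures only
the *area* a biofilm covers and fails outright when foreground and
background intensities overlap, as they do on lightly fouled surfaces.
`bgikit` implements the **Biofilm Growth Intensity (BGI)** score, which
grades the whole intensity distribution of a stained-coupon photograph
instead of cutting it in two, alongside the classic binary comparators,
the optical-density control conversion, and the statistic used to rank
image-analysis methods against independently measured cell density. A
synthetic coupon generator makes the entire pipeline runnable and
testable without laboratory data.

Intended users: microbiologists and biofouling engineers scoring coupon
exposure experiments, and method developers benchmarking image-analysis
metrics against a cell-density control.

## The score

For one channel (grayscale, red, green or blue) of the analysed region
with histogram *h*:

1. ten thresholds `t₁ < … < t₁₀` minimise the count-weighted
   within-class variance (multilevel Otsu, found by exact dynamic
   programming), partitioning intensities into 11 classes;
2. a linear ramp weights the class counts `n_g` — 0 for the brightest
   class up to 1 for the darkest in steps of 1/10 — giving
   `A₂ = Σ_g w_g n_g`, while `A₁` is the total pixel count;
3. `BGI = 100 · A₂ / A₁ ∈ [0, 100]`.

BGI is 100 iff every pixel lies in the darkest class and 0 iff every
pixel lies in the brightest. Methods are ranked against areal cell
density (`cells/cm² = 3.9×10⁸ · OD₆₀₀ · V / (2·side²)`) by the
composite fit `score = r · m` (Pearson correlation × normalised
regression slope, floored at 0 when either is non-positive).

See `docs/methods.md` for conventions, edge cases and the synthetic
image model.

## Worked example

Generate a synthetic exposure series (triplicate coupons at 0, 48, 72,
144 h with paired OD-derived cell densities), score every image, run
the comparator methods, and rank them against the control:

```sh
bgi synth --out series --seed 42
bgi analyze --manifest series/manifest.csv --out bgi.csv
bgi compare --manifest series/manifest.csv --methods otsu,bgi \
            --channels gray,green --out metrics.csv
bgi rank --metrics metrics.csv --control series/control.csv --out ranking.csv
```

The `rank` step prints:

```
 rank     method        r        m    score
    1  bgi/green 0.980392 0.958400 0.939608
    2   bgi/gray 0.979780 0.897731 0.879579
    3  otsu/gray 0.725982 0.531152 0.385607
    4 otsu/green 0.719199 0.523882 0.376775
```

The BGI score on the green and grayscale channels tracks log cell
density closely (r ≈ 0.98) while binary Otsu coverage does not — clean
stained coupons already read ≈30–50 % "coverage" and the measure
saturates as the biofilm deepens. For this seed the grayscale BGI rises
37.4 → 45.3 → 51.0 → 72.3 (triplicate SD 1–4) as mean density grows
4.7×10⁵ → 2.8×10⁸ cells/cm². Per-image JSON reports and
contrast-stretched class images for visual inspection are available via
`bgi analyze --report-dir`.

The same operations are available as library functions
(`bgikit.compute_bgi`, `bgikit.analyze_image`, `bgikit.fit_score`,
`bgikit.rank_methods`, `bgikit.generate_growth_series`, …).

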