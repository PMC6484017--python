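# Methods

`chewmix` quantifies masticatory performance (MP) from the two-coloured
chewing-gum mixing test and runs the repeated-measures statistical analysis
that such studies report.  This note documents the models, the numerical
choices, and what the synthetic data do and do not emulate.

## The measurement model

A chewed red/green gum specimen is flattened to a thin wafer and both sides
are scanned against a light uniform background.  The measurement has two
stages.

### Bolus segmentation

The wafer (bolus) region is isolated by colour, not by shape:

1. The RGB image is converted to CIE L\*a\*b\* (sRGB primaries, D65 white,
   via scikit-image).  The background colour `bg` is the mean colour of the
   mean-shift superpixels containing the four image corners.
2. A distance map `d_i = log(||x_i − bg||₂ + ε)` is formed.  The logarithm
   compresses the colour texture inside the bolus (red, green and blended
   patches are all *far* from grey) while the near-zero background distances
   stay homogeneous.  The paper-style `log ||x − bg||` is undefined at zero
   distance, so an additive `ε = 10⁻⁶` stabilises it; ε only shifts the
   degenerate pixel to `log ε` and preserves ordering.  The log base is
   immaterial: it rescales the k-means input without moving the partition.
3. Scalar k-means with k = 2 splits the distance map.  The two centroids are
   initialised at the 10th and 90th percentiles of the map, which makes the
   nominally stochastic step a pure function of the image — the basis of the
   pipeline's "no systematic error" property (re-processing a batch gives
   byte-identical results, paired-t p = 1.00).
4. The bolus is the cluster whose member pixels lie nearest the geometric
   image centre (ties go to the smaller cluster, since the bolus occupies
   less area than the background in a full scan).  Selection is spatial, so
   it is invariant to contrast inversion.
5. The mask is reduced to its largest connected component and holes are
   filled (one bolus per image; satellite noise would contaminate the hue
   histogram), and the bolus RGB pixels are extracted.

**Mean-shift detail.**  Mode seeking runs in the colour (range) domain on a
regular spatial subsample of the image; the subsample spacing is derived
from `spatial_bw` (default 8 px) and capped at ~900 samples, and converged
modes closer than `range_bw / 2` (default bandwidth 8 Lab units) are merged
before every pixel is assigned to its nearest mode.  Full joint
spatial-range mean shift is quadratic in pixel count and contributes nothing
here beyond the corner-colour estimate, for which colour modes are
sufficient; the colour-domain variant preserves the partition invariants
(uniform image → one cluster, well-separated colours → exact cluster means)
at ~30× the speed.  Cluster means are always recomputed as arithmetic means
of member pixels, so the reported superpixel colours are exact regardless of
the mode-seeking approximation.  If a corner ever fell inside a
bolus-coloured cluster the background estimate would degrade gracefully
rather than fail; this is not special-cased.

### The VhH statistic

Bolus pixels from both sides of a sample are pooled and converted to the HSI
hue angle (0° red, 120° green) using the arccos hue formula.  Pixels whose
max−min channel spread is below 8/255 are excluded: HSI hue is numerically
unstable on the grey axis.  Hues are binned into B = 256 equal bins over
[0°, 360°), and the MP score is the **population variance of the bin-count
vector**:

    VhH = (1/B) Σ_k (c_k − n/B)²  =  Σ_k c_k²/B − (n/B)²

A fully mixed bolus concentrates its pixels in one intermediate-hue bin
(maximal count variance); an unmixed bolus spreads them over two hue
clusters.  Higher VhH therefore accompanies better mixing.  Two consequences
worth keeping in mind:

* VhH scales as n² in the pixel count (maximum `n²(B−1)/B²`), so absolute
  values depend on scan resolution and bolus size.  At ~10⁵ bolus pixels per
  pooled sample the statistic lives at the 10⁷ scale.
* "Variance of the histogram" could alternatively mean the variance of the
  hue *values*; that reading is rejected because it decreases with mixing
  and cannot reach the 10⁷ scale.

Pooling the two sides into one histogram (rather than averaging two VhH
values) uses all pixels symmetrically and yields one MP value per sample;
per-side variances are emitted as diagnostics.  Bin count, chroma threshold
and the side-aggregation rule are configurable.

## Synthetic data

### Wafer images

`generate_wafer` renders a circular bolus (default radius 70 px on a
192×192 px canvas — a desk-scale stand-in for 300-dpi scans; VhH's n²
scaling makes absolute values size-dependent anyway, so all image-level
claims are comparative) on a light grey background, plus i.i.d. Gaussian
channel noise (default SD 4/255).  The bolus is a jittered grid of
`patch_scale_px` (12 px) colour patches, mimicking the spatially coherent
colour regions of a real partly-chewed bolus.  The latent mixing degree
`m ∈ [0, 1]` controls the patch hues:

* each patch starts at the red end (0°) or green end (120°) with equal
  probability, and is rotated toward the circular midpoint (60°, i.e.
  yellow — red/green dyes blend through yellow) by fraction `m` of the
  half-arc along the shorter arc;
* patches additionally carry hue texture: Gaussian jitter with SD
  `hue_jitter_sd·(1−m)` (default 12° at m=0, exactly 0 at m=1).  Without
  this term the hue histogram is a two-spike mixture for every m < 1 and
  the bin-count variance is *not* monotone in m; the contracting texture
  reproduces the empirical behaviour the statistic relies on — the hue
  distribution narrows steadily as mixing completes — while keeping the
  m = 0 (two pure patch populations) and m = 1 (single hue) limits exact.

Patch hue + fixed saturation 0.65 / intensity 0.5 are converted to RGB by
the HSI sector formulas.  The ground-truth mask is the exact blob footprint,
and generation is byte-reproducible from the seed.

Not emulated: press-thickness variation, scanner optics, specular
highlights, shadows, gum sticking to the plastic sheets, and non-circular
bolus outlines.  Passing Dice thresholds on these images therefore shows the
algorithm's correctness under its stated assumptions (uniform background,
one compact bolus), not robustness to acquisition artefacts.

### Cohorts

`generate_cohort` draws a 265-subject, 3-session cohort mirroring the study
design the statistics assume:

    vhh_is = β₀ + β_c(cgc_i) + β_s(s) + β_age·age_i + b_i + ε_is,
    b_i ~ N(0, σ_b²),  ε_is ~ N(0, σ_e²)

Ages are uniform within four age groups (18–24, 25–44, 45–65, 66–90) with
group weights 71/53/70/71 out of 265; chewing-gum consumption (CGC 0/1/2)
and artificial-denture probability are drawn per age group from the
published demographic table, producing the strong old-age → low-consumption
gradient.  Defaults: β₀ = 2.07×10⁷, session effects (8.5, 9.4)×10⁵ for
sessions 2 and 3, CGC effects (3.22, 4.54)×10⁶, age slope −4.51×10⁴ per
year, σ_b = 1.2×10⁶, σ_e = 8×10⁵ — VhH-unit magnitudes taken from the
published effect sizes, so simulated cohorts live on the realistic scale.
The generative model is exactly additive (no interactions, compound-symmetric
within-subject covariance), which is what makes it a useful null/recovery
bench for the ANOVA ε machinery and the GEE.

`render_cohort_images` maps latent vhh to m by min-max scaling over the
cohort (all-equal cohorts map to m = 0.5 with a warning) and renders two
sides per row; the end-to-end rank correlation between latent vhh and
pipeline-recomputed VhH exceeds 0.8 at 30 rows.

## Statistical battery

All procedures follow the conventions of the mainstream commercial package
used for such analyses, so outputs are comparable with published tables:

* **Systematic error** — paired t-test between two processings of one batch;
  identical vectors are defined as (t, p) = (0, 1), zero-variance nonzero
  differences as the degenerate (∞, 0) limit.
* **Normality** — Shapiro–Wilk plus Lilliefors-corrected KS per group
  (estimated-parameter correction; plain KS against a fixed normal would be
  anticonservative).  Lilliefors needs n ≥ 4; n = 3 groups get SW only.
* **η² (age ~ CGC)** — SS_between/SS_total on one row per subject.
* **Mauchly / ε** — W from orthonormal session contrasts of the *pooled
  within-group* covariance (df = N − g), χ² approximation with df = 2;
  ε_GG from the same contrast covariance; ε_HF with the between-group design
  correction `(N(k−1)ε̂ − 2) / ((k−1)(N − g − (k−1)ε̂))`, capped at 1;
  lower bound 1/(k−1).  Verified against an independent implementation in
  the single-group case where conventions coincide.
* **Mixed ANOVA** — Type III split-plot decomposition computed on
  orthonormal within-subject contrast scores with sum-coded group effects
  (equals the unweighted cell-means analysis under imbalance; equals the
  textbook formulas when balanced, checked against a brute-force oracle to
  1e-8).  The correction rule: none if Mauchly p ≥ 0.05, Huynh–Feldt if
  ε_GG > 0.75, else Greenhouse–Geisser; ε rescales degrees of freedom only —
  the F ratio itself is unchanged.  Partial η² = SS_effect/(SS_effect +
  SS_error).  Under a simulated AR(1) non-spherical null the corrected
  SESSION test holds its 5% size (measured within [3%, 7%] at 500
  replicates).
* **Bonferroni session contrasts** — estimated marginal means unweighted
  across CGC groups; SE of a contrast c is `sqrt(c'Sc · Σ_g n_g⁻¹ / g²)`
  with S the pooled within-group session covariance, df = N − g; p×3 capped
  at 1; Bonferroni-adjusted CIs.  Whether published tables used pooled or
  per-stratum error terms is not generally stated; the EMM-based pooled
  choice is the documented assumption here.
* **Welch F / Games–Howell** — computed on all 3N measurement rows (not
  subject means): the published df2 ≈ 356.5 at N = 265 is only consistent
  with measurement-level input.  This pooling ignores the within-subject
  correlation and is anticonservative; it is reproduced deliberately,
  as the convention being mirrored.  Games–Howell uses pair-specific Welch
  SEs and Welch–Satterthwaite dfs with studentized-range p-values and CIs.
* **GEE** — normal family, identity link, subjects as clusters, independence
  working correlation (exchangeable and AR(1) are available as options),
  robust sandwich SEs, Wald χ² = (B/se)² with df 1 and 95% Wald CIs;
  scale is the Pearson-residual dispersion.  Reference levels CGC = 0 and
  Session = 1; sex coded female = 0 / male = 1, dental status natural = 0 /
  artificial = 1 (the coding the published table's sign conventions leave
  ambiguous, hence configurable in interpretation, and the signs of those
  two main effects are not asserted anywhere).  The full term set comprises
  the five main effects and the published two-way interactions; any
  interaction with an empty supporting cell (typically high-consumption ×
  artificial denture) is dropped and reported.  Parameter recovery on
  synthetic cohorts: the age slope is unbiased within Monte-Carlo error and
  robust-SE CI coverage sits in [90%, 99%] over 100 replicates.

## Degenerate inputs and tie-breaks

* Constant distance map (blank image) → explicit "degenerate image" error.
* k-means centre-selection tie → smaller cluster.
* All-achromatic pixel list → error naming the offending side.
* Hue histogram does not pool the 0°/360° seam bins; VhH depends only on
  the multiset of counts, so seam splitting does not change it.
* Cohort validation enforces exactly one row per subject per session and
  positive vhh before any statistic runs.

## Known limitations

* Absolute VhH values from re-rendered images are not comparable with any
  particular published study's values: scan resolution, bin count,
  achromatic handling and side aggregation all shift the scale.  Image-level
  guarantees are therefore property-based (determinism, Dice, monotonicity,
  rank correlation).
* The Welch/Games–Howell measurement-level pooling inherits the
  anticonservatism discussed above.
* The synthetic cohort's compound-symmetric covariance cannot probe the HF
  vs GG distinction on its own (ε ≈ 1 there); the AR(1) null simulation
  covers that regime.
* Mean-shift bandwidths in published pipelines are typically unreported, so
  per-pixel mask equality with any original implementation is not claimable;
  equivalence is at the property level.
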