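# Methods

This note records the quantitative model implemented by `staz`, the
choices made where the assay's published description leaves the design
open, and what the synthetic-data tests do and do not demonstrate.

## Composite steatosis score

Each optical slice of a larva is summarized by three liver-restricted
parameters. With `M` the set of liver pixels, `G` and `B` the green
(neutral-lipid) and blue (normalization) channel intensities:

* raw fluorescence ratio `R = Σ_M G / Σ_M B`. The sum (rather than the
  mean) is used for both channels; since the mask is shared the ratio is
  identical either way — stated here to remove ambiguity.
* droplet density `LD_dens = n_droplets / |M|` (per liver **pixel**);
* droplet area fraction `LD_area = droplet pixels / |M|` ∈ [0, 1].

The ratio is anchored to the control group:
`Ratio = (R − mean_ctrl) / mean_ctrl`, where `mean_ctrl` is the mean of
the per-larva mean raw ratios of control (DMSO) larvae. Anchoring is
**per batch** by default: the membrane-order arm of the assay anchors
per experiment/staining, and the score arm adopts the same scope for
consistency; a `global` scope is available. Each control larva
contributes equally to `mean_ctrl` regardless of how many slices it has,
which makes the mean corrected ratio of control larvae exactly zero in
every scope unit. Corrected ratios and scores may be negative; no
clamping is applied.

The slice score is `400·Ratio + 10000·LD_dens + 100·LD_area` — the
published coefficients, which were set empirically by the assay's
authors to weight the three parameters homogeneously; no attempt is made
here to re-derive them. A larva's score is the arithmetic mean of its
(up to three) slice scores; fewer than three slices triggers a warning
but is accepted. Because the original analysis macros are not published,
the absolute droplet unit (per pixel here) and the segmentation recipe
below are this package's own; score magnitudes are therefore comparable
only across data quantified with one consistent configuration.

## Droplet segmentation

The recipe is deliberately plain and fully parameterized
(`SegmentationConfig`):

1. median smoothing with a disk footprint (default radius 1 px; 0
   disables it);
2. threshold — Otsu computed on in-mask pixels only (default), or a
   fixed value. Otsu on the liver pixels rather than the whole frame
   prevents the dark out-of-liver background from dominating the
   histogram. If the in-mask intensity is constant, the threshold is
   undefined and segmentation returns zero droplets with a warning;
3. 8-connected components of the above-threshold in-mask pixels
   (8-connectivity matches common particle-analysis defaults);
4. components smaller than `min_area_px` are dropped. Default 4 px:
   smaller blobs are at or below the resolution limit of the assay's
   magnification class and are unreliable as droplets;
5. optionally, touching blobs are split by watershed on the distance
   transform.

The pipeline is deterministic, and Otsu-mode output is invariant under
positive rescaling of the intensities (the threshold scales with the
data), which also makes the score robust to per-batch gain differences.

Known limitation: on a liver containing *no* droplets at all, Otsu will
split the noise distribution itself and report spurious foreground. With
the default cohort conditions this affects the ~2% of control slices
whose Poisson draw is zero and adds conservative (control-inflating)
noise; a `fixed` threshold avoids it when absolute calibration is
available.

## Generalized polarization

`GP = (I_ord − I_dis) / (I_ord + I_dis)` per pixel, computed only inside
the liver mask and only where `I_ord + I_dis` reaches an intensity
floor; dim pixels have noise-dominated ratios. The default floor is 2%
of the 99th percentile of the in-mask summed intensity — the published
procedure masks background pixels without giving a number, so the
default is scale-equivariant (GP maps are invariant to overall gain) and
configurable. A larva's GP is the unweighted mean over defined pixels
(whether the original analysis weighted by intensity is not stated; the
simplest reading is implemented). ΔGP subtracts the batch's control mean
GP, so control larvae average exactly zero per batch.

## Group statistics

The larva is the statistical unit; batches are counted and reported but
not modelled as random effects. Summaries are mean ± SEM (sample SD /
√n; undefined for n = 1). Tests:

* **Kruskal–Wallis + Dunn**: H with tie correction (scipy); Dunn z from
  pooled mid-ranks with the same tie term, compared treated-vs-control
  and Bonferroni-adjusted over those comparisons (the "compare to
  control" convention of common GUI statistics packages); an all-pairs
  mode exists. Bonferroni over positively correlated many-to-one
  comparisons is mildly conservative — measured familywise error is
  ≈0.04–0.05 at nominal 0.05 for 2–4 comparisons, drifting lower as the
  comparison count grows.
* **One-way ANOVA + Dunnett**: F from the standard decomposition;
  Dunnett-adjusted p from the multivariate-t distribution (scipy, fixed
  quadrature seed, hence deterministic); raw p is the unadjusted
  two-sided t probability at the pooled residual df. Adjusted p is
  clipped to be ≥ raw p.
* **Two-way ANOVA + Bonferroni**: type-II F tests for both main effects
  and the interaction via the two-factor linear model (statsmodels);
  requested cell contrasts are pooled-variance t tests
  Bonferroni-adjusted over the requested list. A stepwise
  Newman–Keuls-style post-test is deliberately not offered — it lacks
  coherent familywise error control — and Bonferroni contrasts are used
  instead.

Stars: `*` p<0.05, `**` p<0.01, `***` p<0.001 on adjusted p-values.

## Synthetic data generator

The generator reproduces the *statistical* structure of the assay's
images, not larval anatomy:

* an elliptical liver (default 30 × 22 px semi-axes in a 96 × 96 frame,
  ≈2100 px) emitting the blue signal — strong and liver-restricted in
  `transgenic` mode (default level 120 vs background 10), weak in
  `wildtype` mode (autofluorescence);
* circular droplets with Poisson count (default rate 2·10⁻³ per liver
  pixel, ≈4 per slice for controls), Gaussian radii (default
  2.5 ± 0.4 px), intensity 150 over a diffuse green background of 20;
* Gaussian PSF blur (σ = 1 px), then Poisson shot noise plus additive
  Gaussian read noise (SD 2) — droplet SNR ≳ 30.

Droplet placement is rejection sampling (≤1000 attempts per droplet,
then a packing error) with a pairwise separation margin of
`1 + 2·psf_sigma` px beyond touching, so that distinct droplets remain
resolvable after blur and the count ground truth is unambiguous. All
randomness derives from one seed via spawned child streams per larva and
slice. Cohorts deal larvae round-robin over batches, require a control
in every batch, and can apply a log-normal per-batch intensity factor to
exercise the per-batch normalization (the expected raw ratio is
invariant to it).

The truth table records, per larva, the generative droplet rate, exact
LD_dens/LD_area of the rendered disks, and the expected raw ratio
computed from the noise-free blurred channels (Poisson and Gaussian
noise are mean-preserving, so this is the exact expectation of the
channel sums).

GP pairs are generated by inverting the GP formula
(`I_ord = T(1+GP)/2`, `I_dis = T(1−GP)/2`) with optional multiplicative
Gaussian noise per channel; the noiseless inversion is exact.

What passing simulator-based tests shows: the arithmetic, anchoring,
segmentation and statistics behave as specified under a controlled
generative model. What it does not show: performance on real larvae —
the simulator has no anatomy outside the liver, no autofluorescent yolk,
no depth-dependent attenuation, no out-of-focus droplets, no correlated
droplet structure across slices, and droplets are ideal disks.

## Problem sizes and numerical conventions

* Acceptance-style simulations use 96 × 96 images, 20 larvae per group,
  100 replicate cohorts, and 2000-replicate null simulations for test
  calibration (control + 2 treatments, n = 20) — sizes chosen so the
  whole suite re-derives every property from scratch in a couple of
  minutes on one CPU.
* Pixel `(r, c)` spans `[r, r+1) × [c, c+1)`; ROI polygons and simulated
  disks use pixel-center containment. Mask images count any nonzero
  pixel as liver. Channel identity always comes from an explicit
  plane-to-role map, never from intensity heuristics.
* One mask per slice is the general case; a mask shared across a
  larva's slices (as when a single outline is drawn per larva) is simply
  the same file referenced three times in the sample sheet.
* Result tables are written with `%.17g`, so write→read round trips are
  exact for float64.
* Degenerate inputs raise typed errors: empty masks, zero blue signal,
  non-positive control means, batches without controls, GP maps with no
  defined pixels, all-constant ANOVA inputs, empty factorial cells, and
  infeasible droplet packing.
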