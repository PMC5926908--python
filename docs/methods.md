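# Methods

`blisterquant` implements two analysis arms used in human skin-blister
studies of inflammation resolution: quantification of DAB
immunohistochemistry on biopsy sections, and profiling of lipid
mediators (prostaglandins, leukotrienes and the specialized
pro-resolving mediators — lipoxins, resolvins, protectins, maresins) in
blister exudates sampled over a 0–24 h time course. Both arms are
validated against synthetic data with exact ground truth; this note
records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## 1. Brightfield optics and the synthetic slide model

Transmitted-light histology follows Beer–Lambert attenuation: with
incident intensity `I0` and co-localized stain amounts `A_s` with
per-channel extinction vectors `e_s`,

    I_ch = I0_ch * exp(-(A_hema * e_hema,ch + A_dab * e_dab,ch))

The synthetic generator renders 8-bit RGB slides through exactly this
model, adds optional Gaussian sensor noise (`noise_sd`, 8-bit units) and
quantizes after the noise. Extinction vectors default to the widely
used Ruifrok–Johnston H-DAB constants (hematoxylin `[0.650, 0.704,
0.286]`, DAB `[0.268, 0.570, 0.776]`), stored in `defaults.yaml` and
shared between the forward model and the stain-detection stage.

A slide contains:

* a stain-free glass margin at `I0 = (255, 255, 255)`;
* a tissue region (ellipse by default) carrying a faint diffuse
  hematoxylin wash, amount 0.18, which puts the darkest tissue channel
  near grey level 225. This contrast was chosen from brightfield
  physics: segmentation uses fixed grey-level offsets (−15, −10), so a
  realistic counterstained section must be tens of grey levels darker
  than glass for any such fixed-offset scheme to be meaningful;
* elliptical nuclei (default 3 µm semi-axes, ≈28 µm², comfortably above
  the 10 µm² detection floor) with hematoxylin amount 0.9, placed by
  rejection sampling with a 9 µm minimum centroid distance. A bounded
  number of retries guards against overcrowded specifications
  (`SlideCapacityError`);
* for DAB-positive cells, chromogen (amount 0.8) on a cytoplasmic ring
  extending 7 px from the nucleus, restricted to pixels whose nearest
  nucleus is the cell's own, so neighbouring negative cells are not
  contaminated. Membrane/cytoplasmic staining is the pattern expected
  for the lipid-mediator receptors this assay targets; an option places
  DAB on the nucleus as well.

A "merged pair" mode places two nuclei 5.4 µm apart (overlapping, since
their combined radii are 6 µm) to exercise the merged-nucleus
splitting step.

Ground truth records the tissue mask, nucleus and body label rasters,
the planted stain-amount rasters and per-cell positivity, so every
downstream stage can be scored exactly.

What the generator does **not** emulate: chromatic aberration, uneven
illumination, stain gradients, texture inside nuclei, overlapping
tissue folds, and out-of-focus blur. Passing the recovery tests
therefore demonstrates correctness of the algorithmic chain under ideal
optics, not robustness to the full variability of scanned slides.

## 2. Tissue identification

The segmentation operates on the darkest of the three colour channels,
mean-filtered with a 25 × 25 window (value assigned to the central
pixel, reflection padding). Thresholds:

1. initial: `percentile(filtered, 99) − 15`, tissue strictly below
   (tissue is the darker side in transmitted light — the direction is
   asserted on synthetic slides);
2. refinement: `percentile(filtered | background, 10) − 10`; tissue
   strictly above this is reclassified as background;
3. cleanup: connected components (8-connectivity) of tissue and of
   background smaller than 50 µm² are flipped to the surrounding class
   (tissue islands first, then background islands), then tissue
   components under 1% of the total tissue area are removed.

Percentiles use linear interpolation between order statistics; all
comparisons are strict. The stage runs at an internal ×2 block-mean
downsampling by default (segmentation is defined at a coarser
magnification than stain detection); physical units carry the scale, so
all area rules are unchanged. Reflection padding was chosen for the
mean filter because zero padding would darken borders and bias the
percentile thresholds.

Regions of interest default to a tiling of the tissue bounding box on a
near-square grid (4 ROIs → 2 × 2), each tile intersected with the
tissue mask; user-supplied label rasters are accepted verbatim after
tissue intersection.

## 3. Hue–saturation–density stain separation

Per channel, density is `d_ch = −ln((v_ch + 1)/(I0 + 1))`; the +1
regularization keeps the log finite at pixel value 0. Overall density
is `D = mean(d_R, d_G, d_B)` and the chromatic coordinates are
`cx = d_R/D − 1`, `cy = (d_G − d_B)/(√3 D)`, set to zero when
`D < 1e−6` AU (achromatic guard). Every stain's extinction vector maps
to an amount-independent point in the (cx, cy) plane; its polar angle
is the stain's reference hue (hematoxylin ≈ +67°, DAB ≈ −156°).

Stain intensity is `D` multiplied by a trapezoidal angular-proximity
weight: 1 within 15° of the reference hue, falling linearly to 0 at
60°. The flat inner region is deliberate: 8-bit quantization perturbs a
pure-stain pixel's hue by ~1–2°, and a weight that is flat there keeps
the density recovery error bounded by quantization alone (≤ ~0.019 AU
for channel values ≥ 50: a bias of `1/v − 1/(I0+1)` from the
regularization plus ±`0.5/v` rounding, averaged over three channels).
Since the two reference hues are ~137° apart, the 60° cut-off
guarantees a pure pixel of one stain contributes exactly zero to the
other. This weighting is a documented stand-in for an unspecified part
of the original rule set; it is validated only through the synthetic
forward model. It is a per-pixel hue attribution, not a two-stain
linear unmixing: for strongly mixed pixels the split is approximate,
which is also true of the procedure it reproduces.

Derived rasters: `brown+ve = brown − blue` per pixel (may be negative;
downstream rules are strict), and normalized blue = `mean3(blue) −
mean101(blue)` kept only where strictly greater than 0.05 AU. The
large-window mean estimates the diffuse counterstain background, so the
difference enhances the peaks that are nuclei.

## 4. Cell quantification

* **Nuclei**: 8-connected components of normalized blue > 0.1 AU inside
  tissue, area strictly greater than 10 µm².
* **Splitting**: watershed on the negated Euclidean distance transform,
  seeded at h-maxima of the distance map. The seed depth defaults to
  h = 0.5 px: with ~6.7 px nuclei the discretized distance map gives a
  weaker-lobe prominence of only ~0.5–2 px for genuinely merged pairs,
  and h = 1 loses a substantial fraction of them, while h = 0.5
  produced no spurious splits of single convex nuclei in seeded
  experiments. Fragments below the area floor are merged back into
  their largest neighbour; the operation is idempotent on already-split
  rasters.
* **Artifact ceiling**: components above 150 µm² after splitting are
  discarded as large nuclear shapes. No threshold is stated for this
  exclusion anywhere; 150 µm² (~5× a typical leukocyte nucleus) is
  exposed in the configuration rather than hidden.
* **Bodies**: each nucleus is surrounded by cell body grown in
  8-connected geodesic steps through tissue to a depth of 7 px at the
  reference pixel size of 0.45 µm/px. The depth is honoured in physical
  units (≈3.15 µm): at other pixel sizes it becomes
  `round(7 × 0.45 / pixel_size)` pixels. Contested pixels go to the
  Euclidean-nearest nucleus, ties to the lower label id.
* **Positivity**: a pixel is DAB stain where `brown+ve > 0.1` AU; a
  body with > 20% DAB coverage or a nucleus with > 40% DAB coverage
  marks the cell positive (all comparisons strict, exactly as the
  rules are written). Empty regions have coverage 0 with a warning.
* **Densities**: a cell belongs to the ROI containing its nucleus
  centroid; per-ROI density is positive cells per µm² of ROI tissue,
  and the report averages the per-ROI densities (cells whose centroid
  falls outside every ROI stay in the cell table but not in the
  densities; zero-tissue ROIs are excluded with a warning).

## 5. Lipid-mediator profiling

**Identification.** A feature is assigned to a standard when its
retention time matches within 0.1 min and at least 6 of the standard's
diagnostic MS/MS ions are present within 0.01 m/z. Among multiple
qualifying standards the one with the most matched ions wins, ties
resolved by the smaller retention-time difference. The tolerances are
not printed anywhere authoritative; both are config-exposed. The
built-in 20-mediator library uses literature-typical MRM transitions;
its retention times and diagnostic-ion lists are synthetic stand-ins
(flagged as such in the code) adequate for exercising the rules.

**Quantification.** Response = peak area / internal-standard peak area,
inverted through an ordinary least-squares line fitted on the dilution
series 0.78, 1.56, 3.12, 6.25, 12.5, 25, 50, 100, 200 pg. Negative
amounts (response below the intercept) are floored at zero with a
warning.

**PLS-DA.** NIPALS with X-deflation against the centred one-hot
time-point matrix; predictors are centred and unit-variance scaled by
default (the metabolomics convention; pareto and no scaling are
options, since the original scaling choice is unstated). Reported
loadings are the unit-norm X-weights per component — the quantities
shown in metabolomics loading plots. Explained variance is reported
for X and for Y separately. Per-group 95% confidence ellipses on the
two-component score plane come from the group score covariance scaled
by the chi-square(2 df) 0.95 quantile; groups with fewer than three
samples get no ellipse. Missing values are imputed as half the minimum
observed value of that mediator, logged per mediator.

**Temporal testing.** Kruskal–Wallis (tie-corrected, chi-square
reference) across time points per mediator, followed by many-to-one
post-hoc comparisons against the 0 h baseline. The post hoc is Dunn's
rank-based z test with Holm adjustment (configurable): Dunnett's test,
sometimes named in this context, is defined for parametric ANOVA, and
Dunn's many-to-one comparison is the internally consistent
nonparametric counterpart to a rank-based omnibus.

A calibration caveat: the chi-square reference for the omnibus
statistic is asymptotic. At the small group sizes typical of blister
studies (6–7 donors per time point) the test's exact size at nominal
α = 0.05 is ≈0.040 — conservative, never anticonservative. The
type-I-error simulation in the acceptance checks therefore runs at 30
observations per group, where the asymptotic reference applies
(measured size ≈0.049); results at n = 7 remain valid but slightly
conservative.

## 6. Mediator simulation

Concentrations are log-normal, `c = m · exp(σZ − σ²/2)` with
`σ² = ln(1 + CV²)`, so the expected value is exactly
`m = baseline × temporal_effect(t)` and a zero CV reproduces the mean.
Defaults: 20 mediators across the three fatty-acid metabolomes, time
points 0/4/8/14/24 h, 7 donors per time point, baseline 10 pg,
CV 0.3. Numeric exudate concentrations are not available to calibrate
against, so the default temporal profiles encode only the directional
structure reported for this model: onset eicosanoids (PGE2, PGF2a,
TxB2, LTB4 and its further metabolites, with LXB4) peak at 4 h; RvE3
peaks at 8 h; LXA4 rises through the late phase; MaR1 dips at 8 h and
recovers by 24 h; all other mediators are flat. Magnitudes (2–3×
peaks, 0.4× dip) are round numbers of the size such studies report,
not fitted values.

## 7. Numerical conventions

* All thresholds strict (`>` / `<`) as written; percentiles linearly
  interpolated.
* Mean filters: square windows, reflection padding, odd sizes enforced.
* 8-bit quantization in the generator: round after noise, clip to
  [0, 255].
* Watershed ties and label order: deterministic given the input; the
  generators are deterministic functions of their seed.
* Degenerate inputs: empty background (refinement skipped with
  warning), no tissue (empty report, exit 0), empty nucleus/body
  regions (coverage 0 with warning), all-identical concentrations
  (H = 0, p = 1), single time point (PLS-DA refused, temporal tests
  skipped).

## 8. Problem sizes used in the shipped checks

The acceptance checks run on 768 × 768 px slides at 0.45 µm/px with
100 cells (60 DAB-positive), 20 slides for segmentation fidelity, 100
random 64 × 64 fixtures for the classification oracle, 1000 labelled
MS/MS features, 100 simulation seeds for PLS-DA recovery, and 5000
replicates for the type-I-error simulation. These sizes give stable
Monte-Carlo estimates (binomial standard errors below half a
percentage point at the relevant rates) while keeping a full run in
tens of seconds.

## 9. Known limitations

* The hue-weighted stain attribution is not a spectral unmixing; mixed
  hematoxylin+DAB pixels are attributed by hue proximity only.
* Tissue segmentation fidelity is demonstrated on synthetic optics;
  scanner-specific illumination fields would need flat-field
  correction upstream.
* The artifact ceiling (150 µm²) and the ROI tiling are pragmatic
  defaults for a procedure whose original values are unstated.
* Fig-level results of the source assay (receptor-positive cell
  densities in real biopsies, measured exudate concentrations) depend
  on images and samples that are not deposited; the package reproduces
  the procedures and validates them on ground-truthed synthetic data.
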