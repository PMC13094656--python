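# Methods

This note documents the models, conventions and defaults behind `mucospot`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Segmentation model

**Primary objects (nuclei).** The nuclear channel is smoothed with a Gaussian
(`smoothing_sigma`, default 1 px), thresholded (per-image Otsu over a 256-bin
histogram by default, or a fixed manual threshold), hole-filled, and
declumped: local maxima of the Euclidean distance transform, separated by at
least `nucleus_diameter_min`, seed a watershed on the negated distance
transform. Objects whose equivalent diameter `2√(A/π)` falls outside
`[nucleus_diameter_min, nucleus_diameter_max]` (defaults 8–40 px) are
discarded. Labels are assigned in raster-scan order of each object's first
pixel, which makes every segmentation output deterministic.

The declumping variant (distance-transform maxima + seeded watershed) is one
of several used by high-content tools; it was chosen because it is parameter-
light and exactly reproducible. The Otsu threshold is computed in-package
(cumulative between-class variance over the histogram, first maximum on tie
plateaus) so its cut-point semantics are pinned; the test suite checks it
against an exhaustive scan and against an independent library implementation.

**Epithelial region.** The membrane channel is smoothed, Otsu-thresholded,
morphologically closed (disc radius ⌈`smoothing_sigma`⌉), hole-filled, and
cleaned of specks smaller than `nucleus_diameter_min`². A stained crypt
cross-section — a bright annulus — therefore yields the filled outer disc:
the epithelial band *plus the lumen it encloses*, which is the correct region
to exclude when hunting lamina-propria cells.

**Masking rule.** An object is "inside" the region when at least
`mask_min_fraction` (default 0.5, majority rule) of its pixels are; the
epithelial pipeline keeps inside-objects, the lamina pipeline keeps the
complement. The two pipelines therefore partition the nuclei of an image
and can never claim the same nucleus.

**Secondary objects.**
*Epithelial:* seeded watershed on the raw membrane intensity landscape
(marker ridges act as barriers), growth confined to the epithelial region
plus the seed nuclei. *Lamina propria:* every nucleus is dilated by
`expansion_distance` (default 5 px — the marker panel gives no per-cell
boundary outside the epithelium, so a fixed collar is the honest model);
contested pixels go to the nearest nucleus, exact ties to the lower label
(enforced by per-label distance transforms updated in ascending label order
with strict improvement). Pixels inside the epithelial region are never
assigned to a lamina cell, but a nucleus always remains part of its own cell.

**Tertiary objects.** Cytoplasm(L) = cell(L) \ nucleus(L) as a pixel-set
identity; a cell identical to its nucleus yields an empty, flagged
cytoplasm rather than an error.

## Spots

Spots are primary objects of the marker channel: threshold, 8-connected
components, area band `[spot_area_min, spot_area_max]` (defaults 2–200 px),
no declumping. Attribution uses the maximum-overlap child→parent rule.
Compartment attribution runs against a combined map encoding nucleus L as
2L−1 and cytoplasm L as 2L, so the generic lowest-label tie rule classifies
an exact nucleus/cytoplasm tie as nuclear — consistent with the observation
that edge spots get called nuclear under maximum overlap. The whole-cell
assignment is computed independently and exported as well, since the two can
disagree for spots straddling two cells; per-cell summaries use the
compartment attribution so nuclear + cytoplasmic = total holds exactly.

A cell is marker-positive when it carries at least `min_spots_positive`
spots (default 2). `percent_positive` = 100 × positive / total cells.

A deliberately naive second counter (`brute_force_spot_count`, pure-python
scan + stack flood fill, no shared code with the detector) serves as the
in-repo oracle and as the "second software" in agreement analyses.

**Thresholding mode.** Per-image Otsu adapts to staining variation and is
the default. On noiseless, unblurred renders with exactly three intensity
levels, Otsu splits the two *large* classes (background vs diffuse signal)
rather than isolating the small bright class — a classic failure mode of the
criterion — so ground-truth-exact tests use the manual mode with a fixed
threshold; both modes are first-class.

## Measurements

* **Area** — pixel count.
* **Perimeter** — length of the traced outer 8-connected boundary chain,
  orthogonal steps 1, diagonal steps √2. The tracer is a deterministic map
  on (pixel, backtrack-direction) states; the cycle it enters is the closed
  outer contour and its summed step length is the perimeter. A single pixel
  is assigned its crack perimeter 4. Chain length overestimates smooth
  contours by up to ≈ 5% on average for a circle, which puts the form factor
  of rasterized discs in a 0.88–1.05 convergence band — the estimator is
  fixed and that band is asserted, not tuned. (A verbal "count of boundary
  pixels" definition cannot be implemented consistently — it is not additive
  under resolution changes — so a standard estimator anchored to form-factor
  convergence is used instead.)
* **Form factor** — `4πA/P²`; 1 for a perfect circle in the continuous
  limit.
* **Radius** — mean of the Euclidean distance transform over object pixels
  = mean distance to the closest outside pixel; `r/3` for a disc of radius
  `r`. The image border counts as outside.
* **Compactness** — `2π·msd/A` where `msd` is the mean squared pixel
  distance from the centroid. The `2π` normalization calibrates a perfect
  disc to exactly 1 in the continuous limit (`msd = r²/2`, `A = πr²`);
  elongated or ragged shapes score higher (a 1×9 bar scores ≈ 4.7).
* **Radial distribution** — for each cytoplasm pixel the normalized depth
  `d = d_nuc/(d_nuc + d_edge)` (distance to the nucleus pixel set over total
  nucleus-to-cell-edge distance) is binned into `n_radial_bins` (default 3)
  equal intervals; `FracAtD_b` is the fraction of total cytoplasmic marker
  intensity in bin b, `BinAreaFrac_b` the fraction of cytoplasm area. Under
  a uniform marker the two coincide identically. Cells with empty cytoplasm
  or zero marker intensity return flagged null fractions. The two-sided
  normalized depth is the open design choice here; it makes ring widths
  adapt to local cytoplasm thickness, which is what "3 rings between nucleus
  and cell edge" means for non-concentric cells. Both raw-intensity and
  area-fraction columns are always emitted since either normalization is
  defensible.

Objects touching the border get their metrics computed as-is plus a
`TouchesBorder` flag; the lamina pipeline's border filter removes them from
final tables anyway.

## Exclusion filters (lamina pipeline)

Three auditable rules, evaluated in fixed order with the first match
recorded: (1) **oversize** — area > `area_filter_factor` × the image mean
cell area (default factor 3; the mean is a single pass including the
candidate). Only the oversize side is filtered: a merged pair of cells is
oversized, while a small cell is not evidence of mis-segmentation. (2)
**epithelial overlap** — more than `epcam_overlap_max` (default 0.5) of the
cell's pixels inside the epithelial region: the object is an epithelial
cell, not a lamina cell. (3) **border** — any pixel on the first/last row or
column. Kept ∪ removed = input and per-reason counts reconcile with the
total, so filter accounting can be displayed exactly.

## Image quality and deviation

The **focus score** is the normalized variance `var/mean²` of a channel — a
monotone-under-blur sharpness statistic (the name is used by high-content QC
modules without a published formula; this convention is ours and is
documented as such). Also reported: mean/SD/MAD intensity, percent of pixels
at the channel maximum, and the 256-bin histogram. Quality classification is
a two-threshold rule (focus score and intensity SD), calibration-exposed
rather than learned. **Segmentation deviation** is `|auto − manual|` counts,
also as a percentage of the manual count (flagged undefined at manual = 0);
metric-vs-deviation association uses Pearson r with the two-sided t-test
p-value (n − 2 df).

## Agreement statistics

Differences are **automated − reference**, so a negative bias reads as
automated undercounting. Limits of agreement are `bias ± multiplier × SD`
(sample SD, n−1). The multiplier defaults to 1.96 (95% limits) and is
exposed — 2.054 reproduces 96% limits where that convention is wanted.
Stratified agreement bins pairs by their mean `(a+b)/2` into half-open
`[lo, hi)` strata, so a mean exactly on an edge joins the upper stratum.

## Synthetic scenes

The generator renders what the pipelines need to be exercised end-to-end —
one or more annular crypts (membrane band bright, lumen dark), epithelial
nuclei on the ring, lamina nuclei scattered with a minimum separation, and
per-cell marker spots — with ground-truth label maps, compartment classes
and spot counts recorded before noise.

Defaults (one scene): 512×512 px, 1 crypt (inner/outer radius 60/110 px),
18 epithelial nuclei, lamina density 5 per 10⁴ px² (≈ 110 nuclei), nucleus
radius 7 ± 0.8 px with low-order radial Fourier irregularity (amplitude
0.08, harmonics 2–3 — the cheapest shape model that moves form factor and
compactness in a controlled way), spot radius 1.5 px (9 rendered pixels),
cytoplasmic/nuclear spot rates Poisson(4)/Poisson(1), additive Gaussian
noise σ = 0.01 and blur σ = 0.6 on all channels. The "remission-like" group
multiplies spot rate ×1.6, spot radius ×1.4, marker intensity ×1.4, nucleus
radius ×1.15 and irregularity ×1.6 — moderate, clearly detectable effect
sizes for directional tests. The spot-radius multiplier is chosen to cross a
pixel rasterization boundary (1.5 → 2.1 px, 9 → 13 rendered pixels); a
multiplier below ×⅓ of a pixel step would not change the rendered spot at
all. Spot centres keep a minimum separation (2·radius + 2 px) and stay a
spot-radius inside their compartment, and the recorded truth is the count
actually placed — so on noiseless scenes detection can be pixel-exact.
`degrade_quality` blurs and contrast-compresses the membrane channel only,
emulating weak epithelial staining; heavy degradation (σ ≈ 25, contrast 0.1)
moves the Otsu epithelial mask enough to mis-claim boundary nuclei, which is
how the quality→deviation effect arises end-to-end.

**What passing these tests shows** — and does not. The scenes have
well-separated lamina nuclei, concentric crypts, isotropic blur and pixel-
aligned truth, so the benchmark demonstrates correctness of the object
model, the measurements, attribution, filtering and QC plumbing. It does not
demonstrate performance on real tissue: touching nuclei in dense
infiltrates, autofluorescence texture, anisotropic optics, folds and
staining gradients are all absent, and real segmentation error rates will be
higher than the near-zero deviations seen on clean synthetic scenes.

## Determinism and problem sizes

All randomness flows through a single `numpy` Generator seeded from the
scene spec; pipelines themselves draw no random numbers. Identical inputs
and configuration produce byte-identical CSV exports. Tests run on one to a
few 512×512 scenes (a scene renders in ≈ 2 s and a pipeline pass takes ≈ 1 s),
chosen as the smallest geometry in which a crypt, its lumen, and a
surrounding lamina population are all comfortably resolved at the default
nucleus scale.

## Known limitations

* The two secondary-object strategies assume the membrane marker outlines
  the epithelium (watershed barriers) and that lamina cells are adequately
  modelled by a fixed collar; neither is appropriate for tissues without a
  band-like epithelial compartment.
* The maximum-overlap rule biases edge spots toward the nucleus; the
  radial-distribution module quantifies cytoplasmic distribution without
  that bias and should be preferred for localization claims.
* Per-image Otsu assumes a bimodal histogram; images dominated by one class
  (or exactly-three-level synthetic renders) need the manual threshold mode.
* Chain-code perimeters overestimate smooth boundaries by a few percent;
  form factors are comparable within this package but not across packages
  using different perimeter estimators.
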