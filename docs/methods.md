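# Methods

This note documents the models, algorithms and numerical choices behind each
analysis stage, what the synthetic generators emulate (and deliberately do
not), and the design decisions taken where the underlying procedures are
conventionally under-specified.

## Immunofluorescence compartment quantification

Each frame is a calibrated single-channel image (`IntensityFrame`: pixels in
arbitrary units, pixel size in µm/pixel).  The nuclear compartment comes from
the DAPI channel: per-frame min–max normalisation to [0, 1], a global Otsu
threshold, and removal of specks below 10 µm² (configurable).  The cell
footprint comes from the phalloidin channel: normalisation, grey-scale
morphological closing with a disc of radius 6 µm (bridging sub-resolution
gaps in the actin stain; an error is raised if the pixel size exceeds the
element, since the disc would vanish), and Otsu thresholding.  The
cytoplasmic compartment is defined as footprint minus nuclear mask, which
makes the two compartments disjoint by construction — a requirement for
nuclear-vs-cytoplasmic contrasts to be meaningful.  Mean marker intensity is
measured over each compartment; an empty compartment yields NaN and an
explicit flag rather than an exception.

Choices made where the procedure is under-specified:

* **Threshold**: Otsu on the normalised channel — parameter-free and
  standard; a percentile-clipped normalisation is available for data with
  hot pixels.
* **Normalisation scope**: per frame.  Set-wide scaling was considered and
  rejected: Otsu is scale-invariant within a frame, so per-set scaling would
  change results only through clipping.
* **No background subtraction** before mean-intensity measurement; means are
  reported on the raw intensity scale.
* **Frame exclusion** is an explicit user-supplied list of frame
  identifiers (mirroring masked-observer quality control), not an automated
  focus metric.  Set summaries weight frames equally, not by area.

## SAβGal scoring

Cells are segmented from the luminance of the RGB image by thresholding the
Sobel gradient magnitude (Otsu), then dilating the edge map (2 px), filling
holes, and eroding.  The default erosion radius (3 px) exceeds the dilation
radius by the half-width of the Sobel edge band, so the recovered outline
sits on the true boundary rather than one edge-band outside it; on synthetic
discs this reduces the cell-area bias from about +9% to under 2%.

A pixel is SAβGal-positive when it lies inside the cell mask and its HSV hue
falls in the **closed** interval [0.265, 0.58].  Two numerical guards are
applied:

* a minimum-saturation gate (default 0.1, settable to 0 for a literal
  hue-only threshold) — hue is undefined on achromatic pixels, and without
  the gate near-grey noise pixels with arbitrary hue would count as
  positive;
* an interval tolerance of 1e-9 absorbing float round-off in RGB↔HSV
  conversions, far below the hue resolution of 8-bit colour data.

Condition-level aggregation divides pooled positive area by pooled cell
area (not the mean of per-frame fractions), matching the total-area
definition of the readout.

## Neurosphere detection

The per-well chain is rim → illumination → enhancement → detection → filter.

**Well rim.**  A morphological geodesic active contour is initialised as a
disc inset from the frame border and shrunk by a balloon force that releases
at high-gradient structure (the rim).  Convergence is declared when the
level set stops changing across 25-iteration blocks; non-convergence raises
a diagnostic error, with a circular-Hough fallback available via config.
The detected interior is the region enclosed by the rim's inner edge — the
dark rim ring itself is well-wall shadow, not usable area.

**Illumination.**  Microscope shading is multiplicative, so correction runs
in the log-intensity domain where it becomes additive.  The background field
is the mean of the opening-by-reconstruction and closing-by-reconstruction
envelopes (the reconstruction-based top-hat/bottom-hat pair) computed with a
structuring element larger than the largest expected sphere (default
300 µm), so spheres cannot leak into the estimate; working in the log domain
keeps local texture amplitude position-independent under any smooth
multiplicative gradient.  After subtracting the field, a homomorphic
Gaussian high-pass (σ = one maximum sphere diameter) removes residual
gradients, and the result is exponentiated so the background level reads
1.0 regardless of the scene's mean illumination.

**Enhancement.**  A strictly monotone log-domain compression
(`log1p(g·x)/log1p(g)`, g = 3) compresses highlights while preserving the
image's rank (phase) structure, followed by CLAHE (8×8 tiles, clip limit
0.02).  CLAHE's histogram quantisation can introduce rank inversions no
larger than one quantisation step; the tests bound them explicitly.

**Detection.**  Spheres read as patches of raised local Shannon entropy
(sliding disc window, default radius 12 px ≈ half the minimum valid sphere
diameter at the default 2 µm/pixel calibration).  The entropy map is
Otsu-thresholded inside the well, but because an entropy window dilates
object outlines by roughly its own radius, the coarse map is used only to
decide *which* texture regions are spheres: region extent is taken from a
3-px local-standard-deviation map (Otsu-thresholded, closed, hole-filled),
keeping components whose area is at least 30% covered by entropy cores.  A
1-px erosion offsets the half-window dilation bias of the fine map; on
synthetic scenes this leaves projected areas within ~5% of analytic truth
across sphere sizes and pixel sizes.  Touching spheres are separated by
watershed on the Gaussian-smoothed (σ = 4 px) distance transform with
h-maxima seed suppression (h = 2 px) to prevent over-splitting.  Regions
within the boundary band (8 px) of the well edge are discarded as partially
imaged.

**Filter.**  A sphere is an object with circle-equivalent diameter
*strictly greater than* 50 µm and moment-ellipse eccentricity *strictly
less than* 0.8 (regionprops conventions; equivalent diameter is recomputed
from the physical area as 2√(area/π)).  Well summaries report the count,
the projected-area distribution, and a large-sphere count (area
> 1×10⁵ µm²).  Automated identification can be manually confirmed by
editing the per-well sphere CSV (a `keep` column) and re-ingesting it.

## Projected-additive synergy

Raw plate-reader values are divided by the untreated-control mean, so the
control reads 1.0.  Under Bliss independence the expected combination
survival is the product of the single-agent surviving fractions; the
replicate-level projected sample is formed and compared with the observed
combination replicates, and each dose is called synergistic / additive /
antagonistic by the sign and significance of the contrast at α = 0.05
(two-sided).

Two statistical choices deserve note, both validated by Monte-Carlo
simulation against the Bliss-true generator:

* **Matched pairing (default).**  Forming the projected sample as all
  n_a·n_b cross products looks attractive (it uses every pair) but the
  products share factors and are therefore correlated; treating them as
  independent replicates inflates the false non-additive rate to ~14% at a
  nominal α = 0.05 (cv = 0.05, n = 6).  Element-wise products of same-index
  replicates give n independent projected values and a calibrated test
  (~5%); the cross-product mode is retained via config for comparison.
* **Welch contrast.**  The projected sample carries roughly twice the
  relative variance of the observed sample (two noise sources multiply), so
  the two-group comparison uses the Welch t statistic; simulation shows it
  calibrated at 4.9–5.1% where the pooled form runs ~5.5%.

Re-normalising an already fraction-scaled table by its sampled control mean
is harmless to any single contrast but injects the control estimate's noise
once into the observed sample and twice into the projected product; when a
table is already in fraction units the classifier is therefore applied to
it directly.

When several dose levels are tested jointly, Tukey's HSD across the pooled
set of observed/projected groups controls the family-wise error rate
("joint" mode, default); an unadjusted per-dose mode is available.  With
zero within-group variance (noise-free input) the degenerate rule applies:
identical means are additive with p = 1, distinct means classify by
direction with p = 0, both flagged.

## Synthetic generators: what they emulate and what they do not

* **Fluorescence scenes**: cells are discs (nucleus concentric within
  cytoplasm) placed by rejection sampling with a clearance (default 14 µm)
  between cells and from the frame border — the latter so that border
  padding cannot interact with morphological closing.  The marker channel
  takes its nuclear/cytoplasmic means exactly on the truth masks before
  additive Gaussian noise.  Real cells are irregular, touch, and show
  graded intensities; passing tests demonstrate correct quantification
  given separable compartments, not segmentation of confluent cultures.
* **SAβGal scenes**: a contiguous sub-region of exactly
  `round(fraction × area)` pixels per cell is painted at the stain hue
  (region grown from a boundary anchor, contiguous by convexity), the rest
  of the cell at an out-of-window hue, on a brighter near-achromatic
  background.  Chromogen gradients and overlapping cells are not modelled.
* **Well scenes**: spheres are ellipses parameterised by circle-equivalent
  diameter and eccentricity (so analytic area is π·d²/4 regardless of
  elongation), filled with bounded-amplitude pixel-wise uniform texture —
  the property the entropy detector keys on — over a smooth background,
  with a dark rim ring, a linear multiplicative illumination gradient,
  radial vignetting, and additive Gaussian noise.  Optical blur,
  out-of-focus debris and sphere halos are not modelled.
* **Viability tables**: replicates are Gaussian with a fixed coefficient of
  variation around true group means (control 1.0); the combination truth is
  f_a·f_b shifted by ±`interaction_shift` for synergistic/antagonistic
  scenarios.  Plate edge effects and heteroscedasticity are not modelled.

Determinism is a contract throughout: a generator spec embeds its seed and
reproduces bit-identical output; every pipeline stage rerun with identical
inputs, config and seed writes byte-identical CSVs.

## Problem sizes and defaults

Default synthetic conditions: 256×256 px fluorescence frames at 1 µm/pixel
with ~12 cells (nuclear radius 8 µm, cytoplasm 15 µm, marker means 200/100
over background 10); 256×256 px RGB scenes with ~6 cells of radius 20 µm;
560×560 px wells at 2 µm/pixel (well radius 480 µm) with spheres of
40–160 µm.  Verification batches use 20 frames / 50 stained images / 20
wells / 20 sphere pairs / 500 synergy simulations per condition, sizes at
which every recovery and calibration figure is stable across seeds.  The
optical calibration of the original instruments is not published, so all
µm-dependent parameters are configuration values rather than constants.
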