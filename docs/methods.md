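# Methods

This note records the models, algorithms and design choices behind
`stomakit`, and what its synthetic validation does and does not show.

## Optical calibration

A magnification profile carries four constants per lens: pixel density
(px/mm), field-of-view width and height (mm) and resolving power (µm). The
three built-in profiles describe the handheld-microscope lenses the
package targets (100×: 198 px/mm, 2.87 × 2.17 mm, 4 µm; 200×: 415 px/mm,
1.36 × 1.03 mm, 2 µm; 400×: 652 px/mm, 0.75 × 0.57 mm, 1 µm). Lengths are
reported in µm, areas in µm² and densities in mm⁻², the conventional units
of the stomatal literature. Density uses the full optical field of view as
its denominator — each capture images exactly that leaf area — with an
explicit override for cropped or tiled images. If an image's pixel
dimensions disagree with FOV × px/mm by more than 5% a warning is logged
but the profile remains authoritative, since capture software may
letterbox or rescale. Lens distortion and non-square pixels are not
modelled, and the relation between printed FOV and printed px/mm is taken
at face value (sensor pixel dimensions are not published for these lenses).

## Synthetic leaf scenes

The generator exists to make the whole chain testable with exact ground
truth. Two patterning archetypes are modelled. *Rows*: stomata on parallel
files at a fixed pitch, axis-aligned orientations with small Gaussian
jitter, dumbbell-shaped complexes — graminoid patterning. *Scattered*: a
hard-core point process (sequential rejection with a minimum
centre-to-centre distance) with uniformly random orientations and
elliptical complexes — dicot patterning. The expected stomate count is
target density × imaged area (Poisson-drawn in scattered mode,
deterministic per-row allocation in rows mode); if rejection sampling
cannot place the requested count, a packing error names the achieved and
theoretically achievable density (2/(√3·s²) for hard-core spacing s).

Default archetype dimensions — graminoid-large 60 ± 6 µm × 28 ± 3 µm
complexes, graminoid-small 24 ± 3 µm × 11 ± 1.5 µm, dicot 26 ± 3 µm ×
18 ± 2.5 µm, openness (aperture width / complex width) ≈ 0.3 — are
**configurable defaults justified only by the qualitative size ordering of
real material** (wheat stomata are much larger than rice or tomato); they
are not measured species values and cannot be validated against published
dimensions, which are not reported for these imaging conditions.

Rendering is 8-bit grayscale (colour carries no information for any
downstream step): a textured epidermal background (0.78 of full scale),
complex fill at 0.60 with a dark outline (0.34) and a near-black aperture
ellipse (0.12) whose width is openness × complex width and whose length is
0.6 × complex length. Bright soft-edged discs emulate the air-bubble
artifacts of imprint-based sampling. Optical blur is Gaussian with
sd = resolving power in px / 2 — the resolving power is treated as
roughly the FWHM of the point-spread function and halved as a simple
conservative stand-in, since the true PSF is not published. Then a
multiplicative linear illumination gradient and additive Gaussian sensor
noise (sd on the 8-bit scale, default 6) are applied. Every scene is a
pure function of its spec including the seed: re-rendering is
bit-identical. Complexes that would cross the image border are culled by
default (ground truth stays unambiguous); a keep-clipped mode exists for
robustness tests. Ground-truth trait lengths/widths are the exact extents
of the silhouette polygon; areas are its shoelace area, so polygon and
stored traits agree to rasterization tolerance.

Passing against this generator demonstrates that the software chain is
correct and self-consistent at realistic scales, noise levels and
densities. It does not demonstrate performance on real leaves: real
micrographs have pavement-cell relief, trichomes, focus variation and
staining the generator does not attempt (non-goals, along with
photorealism and multi-focal stacks).

## Classical detection

The deep detectors used in production phenotyping are deliberately out of
scope (they need GPUs and training data); `stomakit` instead ships a
deterministic classical detector plus file adapters for external
detections. The detector band-pass filters the image at the expected
stomatal scale (difference of Gaussians at σ = L/8 and L/2), correlates
it with a small bank of synthetic stoma templates (one per configured
orientation, rendered by the scene generator at the profile's scale), and
converts local maxima above `match_threshold` (default 0.5) into boxes
with the axis-aligned extent of the expected complex at that orientation.
Because normalized cross-correlation is contrast-invariant, faint
background texture can score as high as a real stoma; the raw NCC score is
therefore damped by two physical factors: the local band-pass energy
relative to the template's own contrast, and a darkness prior — after
flat-field normalization by a wide surround (which also cancels the
illumination gradient), the stoma core at its minor-axis scale must be
darker than its surround by a minimal relative contrast (15%). Greedy NMS
(default IoU 0.3 — stomata are non-overlapping organs, so aggressive
suppression is safe; ties broken by larger area then input order for
determinism) removes duplicates. An expected complex length below 4 px at
the active profile is refused with advice to use a higher magnification —
small-stomata material is only workable at the highest lens.

Box convention everywhere: 0-based pixel coordinates, origin top-left,
half-open [x, x+w) × [y, y+h); this makes area and IoU arithmetic
unambiguous. The external-detection dialect is one line per box,
`class cx cy w h [conf]`, normalized to [0, 1]; a missing confidence reads
as 1.0 and adapters accept all rows, leaving threshold sweeps to the
evaluation module.

## Segmentation and trait measurement

Each detected box is cropped with 25% padding. Within the crop, intensities
are smoothed (σ = 0.4 px; heavier smoothing measurably degrades the
smallest stomata) and split into three classes — aperture/outline,
complex interior, background — by multi-Otsu; the upper threshold bounds
the complex and the lower isolates the aperture. Because either estimator
can land inside the complex when one class dominates a small crop, the
complex threshold is the brighter of two-class Otsu and the multi-Otsu
upper threshold. After closing and hole-filling, the connected component
nearest the crop centre (among those at least ¼ the size of the largest)
is kept. The outline polygon is the closed sub-pixel iso-contour of the
smoothed image at the complex threshold whose enclosed area best matches
the selected component — several nested iso-contours can enclose the
centroid (outer edge, fill boundary, aperture), so contour choice matters.
Blur pushes the iso-contour of a dark-rimmed object slightly outward; the
polygon is offset inward by 0.4 × the effective blur sd, a proportionality
calibrated once against generator ground truth and held fixed.

The aperture candidate is the largest sub-threshold component of the
complex interior (interior = complex eroded by the nominal outline width,
3 px); it is accepted only if its area is ≥ 2% of the complex and its
moment-ellipse elongation ≥ 2 — both defaults chosen to suppress
specular-speck false apertures. "Stomatal size" is the area of the full
complex outline including subsidiary cells (the annotation convention the
adapters expect); guard-cell-only area is out of scope. Lengths and widths
are the full axes of moment-equivalent ellipses computed **analytically
from the polygons** (Green's-theorem area integrals; an elliptical polygon
recovers its own axes exactly, with no rasterization error, and the result
is invariant to vertex order). For dumbbell-shaped complexes the moment
ellipse's major axis slightly underestimates the tip-to-tip extent; areas
are unaffected. The headline aperture scalar is aperture length, with
width, area and openness (aperture width / complex width) also reported,
since which scalar a given lab plots varies. Detections touching the image
border are counted (preserving density) but excluded from size and
aperture statistics, since truncated organs bias size distributions.
Failures (blank crops, degenerate polygons) produce flagged
`status="failed"` records, never exceptions, so one bad stoma cannot abort
a batch.

## Evaluation

Predictions are matched to ground truth greedily in descending confidence
(ties: higher best-available IoU, then input order); each prediction
claims the unmatched ground-truth box of highest IoU and the pair is
accepted iff IoU ≥ 0.5 (the conventional criterion for this detector
family; the value is configurable). Precision is TP over all detections,
recall TP over all true stomata, F1 their harmonic mean. With zero
predictions precision is 1.0 (no false claims were made) and recall 0;
zero-ground-truth images give recall 1.0. Greedy matching was chosen over
optimal assignment because it is the standard of detector evaluation
practice; an exhaustive-search oracle in the test suite bounds the
difference (greedy TP ≥ optimal TP − 1 on instances up to 6 × 6, with
exact equality whenever no box competes for more than one partner).
Confidence curves re-match at 101 evenly spaced thresholds and report the
F1-maximizing threshold (ties to the lowest). mAP is deliberately not
computed — single-threshold P/R/F1 is what this workflow reports.

## Comparison and screening

Automated-vs-manual agreement is quantified by ordinary least squares of
automated (y) on manual (x) values with intercept, reporting slope,
intercept and R² — slope and intercept make calibration bias visible even
when R² is high. Counts are compared per image; sizes and apertures as
per-image means, because no per-stoma correspondence across methods
exists. The contrast screen ranks image summaries by stomatal density,
returns the top and bottom quantile groups (default 0.2; ties broken by
image id; the two groups together hold ⌈2qn⌉ units) and reports the
Spearman rank correlation between density and mean complex area, computed
by an explicit rank transform (scipy's implementation serves as an
independent cross-check in the tests). Agreement statistics beyond OLS
(concordance coefficients etc.) are extension points, not implemented.

## Problem sizes and numerical choices

The validation suite and the acceptance script run full scenes at the
400× profile's native 489 × 372 px field of view, at 50 mm⁻² (large
graminoid) and 100 mm⁻² (dicot) densities with noise sd 6 and a 15%
illumination gradient — 20 scenes per archetype in the test suite, 12 in
the acceptance script, a few hundred stomata per batch, which gives
stable pooled statistics while keeping a full run on one CPU in tens of
seconds. Scene seeds derive deterministically from the run seed. All
thresholds and defaults above (match 0.5, NMS 0.3, evaluation IoU 0.5,
smoothing 0.4 px, aperture gates 2%/2.0, edge-bias 0.4σ) are fixed in
code and documented here rather than tuned per dataset.

## Known limitations

* The classical detector and threshold segmenter are validated on
  synthetic scenes; on real micrographs they are a starting point and a
  reference implementation, not a replacement for a trained detector —
  the file adapters exist precisely so trained-model outputs can be
  evaluated and measured with the same tooling.
* Stomata near the resolving limit (graminoid-small at 400×: complexes
  ~16 × 7 px) measure with noticeably higher relative error; area
  recovery remains unbiased but per-stoma R² drops — consistent with the
  practical rule that small-stomata species need the highest
  magnification available.
* The moment-ellipse length of dumbbell complexes underestimates
  tip-to-tip extent by a few percent.
* Conductance modelling (g_max), morphotype classification, video-based
  aperture dynamics and pavement-cell segmentation are out of scope.
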