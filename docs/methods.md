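# Methods

This note records the models, parameter choices and numerical decisions
behind `cryptmorph`, in the order the pipeline runs them.

## Image model and synthetic scenes

SHG signal arises from fibrillar collagen, which in colonic mucosa forms
the network *between* crypts. A scene is therefore modelled as a bright
background (collagen) with dark lumens punched out: pixels inside a
crypt polygon are drawn at `lumen_intensity` (default 2500 counts),
everything else at `background_intensity` (default 9000 counts), with
additive Gaussian read noise and clipping to the 14-bit range
[0, 16383]. The acquisition geometry follows the imaging convention the
package targets: 512×512 px covering 522 μm (pitch 522/512 ≈ 1.02 μm/px),
depth stacks of five planes at 20–100 μm in 20 μm steps.

Each crypt lumen is a rotated ellipse with a sinusoidal boundary
perturbation `r(θ) = r₀ + A·sin(kθ + φ)` — the simplest periodic model
of a serrated edge. Three presets encode the qualitative phenotypes:

| preset | crypts/field | lumen radius (μm) | aspect ratio | serration (A μm, k) |
|---|---|---|---|---|
| normal | 40 | 16 ± 2 | 1.15 ± 0.08 | none |
| tumor_adjacent | 25 | 18 ± 8 | 1.8 ± 0.4 | 3, 9 lobes |
| tumor | 0 | — | — | — |

The literature gives no quantitative morphology for these cohorts (no
deposited images), so the presets are chosen to be biologically
plausible for murine colon — crypt centres ~50–70 μm apart, lumen radii
in the tens of μm — and, more importantly, to produce the qualitative
contrasts the analysis is meant to detect: the tumor-adjacent preset
mixes abnormally large and small crypts (high per-image area SD),
elongates them, and serrates their boundaries; the tumor preset renders
collagen signal with no crypt structures at all. The default noise SD
is 325 counts = 5% of the lumen/background contrast.

Placement is rejection sampling: radius (truncated at 3 μm), aspect
ratio (clipped at 1), orientation and serration phase are drawn per
crypt; a candidate is accepted if its polygon stays ≥ 1 px inside the
field and keeps a minimum edge-to-edge distance (polygon distance, not
centre distance) to all accepted crypts. A density check before
sampling rejects infeasible requests outright, and a capped retry count
(200/crypt) converts hard packings into a recorded shortfall instead of
an unbounded loop. Depth stacks reuse one layout across planes (crypt
identity persists through depth); an optional per-depth radius scale is
available but off by default, since depth-dependent geometry is not part
of the modelled design. Noise is drawn independently per plane.

What the generator deliberately does **not** emulate: optical physics
(PSF, polarization, depth attenuation), Poisson shot noise, collagen
texture, crypt branching, and out-of-plane structure. Passing tests on
these scenes therefore demonstrate correctness of the measurement chain
— segmentation recovering known geometry, features matching analytic
values, statistics calibrated under a known hierarchy — not performance
on real tissue, where contrast, texture and annotation noise are all
harder.

## Segmentation and threshold optimization

Images are affinely rescaled to [0, 1] (`(v − min)/(max − min)`;
constant images are flagged degenerate and mapped to zero). Because
lumens are dark, foreground is `intensity < t`, followed by, in order:
morphological opening (disk radius 2 px by default), hole filling,
removal of components smaller than `min_area_um2`, and removal of
border-touching components (partial crypts bias area and shape
features; on by default). Connected components use 8-connectivity and
are labelled in raster-scan order of their first pixel.

The crypt detection sensitivity (CDS) scores a segmentation against
annotated crypt centres: a point matches a labelled object if it lies
inside it or within 5 px of its nearest pixel (the matching tolerance
absorbs small annotation offsets); assignment is greedy one-to-one by
increasing distance so one object cannot absorb several points.
CDS = matched/total is a pure sensitivity — no false-positive penalty —
so the optimizer breaks ties toward the *lower* threshold (and then the
lower minimum area), which is the less permissive of the tied settings
for dark-lumen foreground. `optimize_thresholds` evaluates the full
parameter grid exhaustively (no heuristic search) and maximizes CDS
pooled over images (total matched / total annotated).

## Morphometry

All features are computed in pixels and converted by the pitch at the
module boundary; coordinates are 0-based, x = column, y = row.

- **Area**: pixel count × pitch².
- **Perimeter**: Crofton estimator (4 directions). A chain-code trace
  through boundary-pixel centers overestimates the perimeter of smooth
  shapes by several percent, which would depress circularity of a
  rasterized disk to ≈ 0.89; the Crofton estimate keeps it within a few
  percent of 1 (measured 0.96 for a radius-20 disk), so circularity is
  interpretable on the conventional 0–1 scale. Tests cross-check it
  against a traced marching-squares contour at a loose tolerance.
- **Circularity** `4πA/P²`; undefined (NaN) for single-pixel objects.
  Rasterization can push it slightly above 1.
- **Eccentricity** `√(1 − (b/a)²)` with semi-axes from the normalized
  second central moments of the pixel set, including the 1/12
  unit-square correction so even a one-pixel-wide line has b > 0.
- **Nearest neighbor**: minimum centroid-to-centroid distance to any
  other crypt; an isolated crypt's value is *undefined*, not zero —
  imputing 0 or the field diagonal would bias cohort means.
- **Centroid distance function**: mean/min/max distance from the area
  centroid to boundary pixels, where boundary pixels are foreground
  pixels with a 4-connected background neighbour; the mean is over
  boundary pixels (not arc length), which slightly overweights corners
  on coarse rasters.

Per-image summaries report the mean and the *sample* SD (n−1) of each
feature over crypts, with NaNs excluded pairwise; the SD is the
within-image heterogeneity statistic. SD needs ≥ 2 defined values, the
mean ≥ 1; a zero-crypt image keeps its row with `crypt_count = 0` and
NaN statistics, written as `NA` in CSV output.

## Cohort statistics

The experimental unit is the mouse: images are replicates within mice,
mice within cohorts. The nested one-way ANOVA tests the cohort mean
square against the mouse-within-cohort mean square (sequential sums of
squares; for balanced designs this is algebraically the one-way ANOVA
on per-mouse means, which the tests verify to machine precision).
Unbalanced tables are handled by the same sequential decomposition; a
cohort with a single mouse is an error (no denominator df), and a table
with zero mouse-stratum variance is flagged degenerate rather than
tested. Location/stack is carried as a label but not added as a third
stratum in the one-way analysis.

The depth analysis is a split-plot: stacks (one location on one mouse)
are whole plots carrying all five depths, so cohort keeps the
mouse-level error while depth and cohort × depth are tested against the
within-stack residual. It requires exactly one observation per
(stack, depth) and a complete depth set per stack, and errors with the
offending stack list otherwise. Per-depth cohort contrasts re-run the
nested one-way ANOVA on each depth slice; per-cohort depth contrasts
treat stacks as blocks.

Tukey HSD operates on per-mouse means with the studentized-range
distribution, Tukey–Kramer SEs for unequal cohort sizes, and the
mouse-stratum df; with two groups it reduces exactly to the pooled
two-sample t-test (q = t√2). Flags follow the `*` p < 0.05 /
`**` p < 0.01 convention with strict inequalities. The feature screen
(7 features × {mean, SD} = 14 analyses) applies no correction across
screens — each feature stands on its own, and the report says so.

## Calibration and problem sizes

Monte-Carlo checks simulate responses directly from the nested
variance-component model (`y = cohort + mouse + noise`) rather than
rendering images, which makes large replicate counts cheap: type-I
error of the nested ANOVA is estimated from 2000 null replicates of a
5-cohort × 4-mouse × 5-image design (observed ≈ 0.054 at α = 0.05, well
inside the [0.03, 0.07] Monte-Carlo band); the split-plot depth test
uses 1200 replicates; the localized-shift power check (a 2-SD cohort
offset at a single depth) uses 120 replicates and detects at > 0.8.
Image-based checks use two full 512×512 scenes per condition for
segmentation recovery and 128-px single-crypt fields for the shape
oracles. The bundled demo design (five cohorts × 2 mice × 1 stack on
128-px fields) exists to exercise the full pipeline quickly; its small,
serrated tumor-adjacent crypts are intentionally hard to segment, so
its pooled CDS (~0.75) is not a benchmark number.

## Known limitations

- Phenotype presets are plausibility-calibrated, not fitted to tissue;
  absolute feature values carry no biological authority.
- The intensity model is two-level plus Gaussian noise; algorithms that
  exploit texture or shot-noise statistics cannot be evaluated here.
- Sequential SS with the mouse-stratum error is exact for balanced
  designs and a documented approximation for unbalanced ones; a
  mixed-model (REML) treatment is out of scope.
- CDS measures sensitivity only; a segmentation that over-detects is
  not penalized, which is why the optimizer's tie-break and the
  morphological cleanup matter.
- No 3D: depth planes are segmented independently, and crypts are not
  tracked across depth.
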