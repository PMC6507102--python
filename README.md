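# cryptmorph

Quantitative crypt morphometry for en-face second-harmonic-generation
(SHG) images of colonic epithelium.

In the colon, fibrillar collagen surrounds the tubular glands (crypts)
of the epithelium, and SHG microscopy images that collagen without any
label: en face, crypts appear as dark, roughly elliptical lumens against
a bright collagen background. Early dysplasia distorts this geometry —
crypts enlarge, elongate, develop serrated edges, and their spatial
arrangement loosens — so the shape and distribution of segmented crypts
is a candidate optical biomarker for colitis-associated and spontaneous
colorectal cancer. `cryptmorph` implements the complete analysis chain
for such studies, for image analysts and microscopists who want a tested,
reproducible reference pipeline that runs without any proprietary data:

1. **Synthetic scene generation** (`cryptmorph.scenes`, `cryptmorph.cohort`)
   — seeded SHG-like crypt fields with exact ground truth, phenotype
   presets (*normal*, *tumor-adjacent*, *tumor*), five-plane depth stacks
   (20–100 μm) and the full cohort → mouse → location hierarchy.
2. **Segmentation** (`cryptmorph.segmentation`) — intensity rescaling to
   [0, 1], dark-lumen thresholding with morphological cleanup, and
   exhaustive grid optimization of the threshold parameters against
   annotated crypt centres, scored by the **crypt detection sensitivity**
   (CDS): the fraction of annotated crypts recovered.
3. **Morphometry** (`cryptmorph.morphometry`) — per-crypt features:
   area, circularity `4πA/P²`, eccentricity `√(1 − (b/a)²)` of the
   moment-fitted ellipse, nearest-neighbor centroid distance, and the
   centroid distance function (average / min / max distance from
   centroid to boundary pixels), summarized per image as mean and
   sample SD.
4. **Cohort statistics** (`cryptmorph.stats`) — nested one-way ANOVA
   (cohort tested against the mouse-within-cohort stratum, so multiple
   images per mouse do not pseudoreplicate), split-plot two-way ANOVA
   for cohort × depth, and Tukey HSD post-hoc comparisons with
   `*` (p < 0.05) / `**` (p < 0.01) flags.
5. **Pipeline** (`cryptmorph.pipeline`, `cryptmorph` CLI) — an
   end-to-end, manifest-checksummed run that is byte-identical under a
   fixed seed.

## Worked example

`examples/02_segment_and_measure.py` generates a default 512×512 px,
14-bit normal-mucosa scene (522/512 μm/px), optimizes the binarization
threshold against the ground-truth crypt centres, and prints:

```
optimized threshold t=0.3, min area=100.0 um^2
crypt detection sensitivity: 100.0% of 40 crypts

segmented 40 crypts; per-image summary:
  area_um2     mean= 865.623  SD=243.171
  circularity  mean=   0.995  SD=  0.015
  eccentricity mean=   0.472  SD=  0.126
  nn_um        mean=  54.173  SD= 13.707
  cdf_avg_um   mean=  15.994  SD=  2.376
  cdf_min_um   mean=  14.452  SD=  2.307
  cdf_max_um   mean=  17.573  SD=  2.576
```

Every annotated crypt was recovered (CDS 100%), mean crypt area is
≈ 866 μm² (lumen radius ≈ 16 μm), circularity sits near 1 as expected
for near-circular crypts, and crypt centres are ≈ 54 μm apart. The SD
columns quantify within-image heterogeneity — the statistic that
separates tumor-adjacent fields (mixed large/small, serrated crypts)
from normal mucosa. `examples/03_cohort_statistics.py` carries those
summaries into the nested ANOVA + Tukey screen across five simulated
treatment cohorts; `examples/04_full_pipeline.py` runs everything end
to end.

The same stages are scriptable from a shell:

```bash
cryptmorph simulate --design demo --seed 1 --out scenes/
cryptmorph run-all --seed 1 --out run/
```

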