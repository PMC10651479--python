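# Methods

## The measurement being modelled

In real-time deformability cytometry (RT-DC) a single-cell suspension is
driven through a narrow microfluidic constriction in a high-viscosity
buffer. Shear stress and pressure gradients deform each cell as it
transits, and a high-speed camera captures one brightfield frame per cell
(a 250 × 80 px region of interest). The analysis never sees the cell at
rest: all features describe the deformed, flowing cell. For heterogeneous
tissue-derived cells — which are not spherical before entering the channel
— no elastic modulus can be inferred, so deformation is treated as a
qualitative deformability readout, and the package deliberately stops at
the feature level rather than fitting a mechanical model.

## Per-cell features

Given the cell contour (an ordered pixel-coordinate polygon) and the frame:

- **area** `A_c`: shoelace polygon area × pixel_size². Default pixel size
  0.34 µm/px, typical for this instrument class; always overridable
  because acquisition optics vary.
- **deformation**: `1 − 2·sqrt(π·A_hull)/P_hull`, computed on the convex
  hull of the contour (the community convention; the hull suppresses
  pixel-level roughness that would otherwise inflate the perimeter). A
  raw-contour mode (`use_hull=False`) is available.
- **area ratio**: `A_hull / A_c` ≥ 1; sensitive to concavities, the main
  debris discriminator.
- **aspect ratio**: max/min of the axis-aligned bounding-box extents, so
  the value is ≥ 1 whichever axis the object is elongated along and the
  "1:2" gate reads simply as aspect ≤ 2.
- **brightness mean/SD**: statistics of pixel values strictly inside the
  contour, in raw camera units (instrument-internal brightness offsets are
  unpublished, so no normalization is attempted).

Segmentation of a frame: background subtraction (a reference frame if
available, otherwise the frame median as a flat estimate), Otsu threshold
on the absolute difference, hole filling, removal of objects under 10 px,
and the outer boundary of the largest connected component. Sub-pixel
boundaries come from marching squares at the 0.5 mask level.

For deformation only, the pixel-step boundary is smoothed with a 5-point
circular moving average before taking the hull: on rasterized smooth
shapes the staircase otherwise biases the hull perimeter upward by
~0.01–0.015 deformation units at 8–20 px radii, while the smoothing
brings the worst-case error under 0.01 without touching the area
estimate (the raw contour is kept for area, area ratio and aspect ratio,
whose pixelation bias is much smaller). Analytic polygons passed directly
to `shape_features` are not smoothed by default.

## Gating

An event is kept iff

    area ≥ 25 µm²  AND  area_ratio ≤ 1.1  AND  aspect ≤ 2
    AND (area ≥ 60 µm²  OR  area_ratio ≤ 1.05)

Each rejected event is labelled with the first failing rule, in that
order, so gate audits are reproducible. The 20 µm² acquisition floor and
the 25 µm² debris cut are both configurable; the analysis gate uses
25 µm² as the effective keep threshold, and tumour analyses may add an
`analysis_min_area` floor of 60 µm² (below which dissociated colon is
mostly immune cells and small debris). Doublet flags (aspect > 2 and area
above a configurable floor, default 50 µm²) are informational: doublets
already fall outside the cleaned single-cell pool under the default
aspect gate, matching the practice of analysing them separately. The
doublet cutoffs are declared assumptions — the reference workflow does
not print them.

Fluorescence positivity: threshold at the 0.99 quantile of an unstained
control from the same tissue, positives strictly above. The quantile is a
declared default (the reference workflow only states that thresholds were
adjusted on unstained samples); 0.99 keeps the false-positive rate at 1%
by construction.

## Sample featurization

Cells are binned by area into closed intervals that may overlap — the
published mouse-colon scheme (60–90, 80–120, 120–400 µm²) overlaps at
80–90 µm², and the package reproduces that literally rather than
"fixing" it; events in the overlap contribute to both bins. Per bin and
feature, the mean, median and sample SD (n−1) are recorded in a fixed
order (bins outer, features middle, statistics inner). Presets:

| preset | bins (µm²) | features | length |
|---|---|---|---|
| `mouse_colon` | 60–90, 80–120, 120–400 | area, deformation, aspect, area ratio | 36 |
| `human_fresh_colon` | 20–50, 50–600 | all six | 36 |
| `human_frozen_colon` | 20–100, 100–600 | all six | 36 |

The frozen-colon preset is a declared reconstruction: the exact published
45-parameter list for that tissue appears only in supplementary material
and is not tabulated, so a below/above-100 µm² split over all six
features is shipped instead, fully configurable.

Bins holding fewer than `min_events_per_bin` (default 10) events yield
NaN entries and an incomplete flag (an error in strict mode); at matrix
assembly NaNs are imputed with the cohort column median, since PCA cannot
take missing values and sparse bins carry no better information.

## Classification

Training: per-column min-max scaling to [0, 1] (constant columns scale to
0 and are excluded from importance), PCA by full SVD of the mean-centred
scaled matrix keeping two components, logistic regression (L2, C = 1,
deterministic lbfgs) on the two scores. No class weighting and no
cross-validated model selection — with 16-pair cohorts there is no budget
for it, and the procedure mirrors the fixed reference pipeline. PCA signs
follow the convention that each component's largest-magnitude loading is
positive, making loadings and score plots reproducible across runs.

Blind samples are scaled with the *training* min/max — values may leave
[0, 1] and are deliberately not clipped, since out-of-range evidence is
evidence — then projected and scored; the probability cutoff is fixed at
0.5. Feature importance is the absolute loading per parameter, normalized
to max 1 within each component.

Robustness analyses: `min_cells_curve` subsamples n events without
replacement, re-featurizes and re-predicts (reps × samples per grid
point), locating the minimum cell count for stable classification;
`mixture_titration` pools f·n disease + (1−f)·n healthy events to
emulate biopsies with partial tumour content.

## Group statistics

Mann–Whitney U (midrank ties) and Wilcoxon signed-rank (W⁺ reported,
zero differences dropped) with exact P by full enumeration for small
inputs (n·m ≤ 64 assignments; ≤ 12 pairs → 2ⁿ sign patterns), defined as
the probability of a deviation from the null mean at least as large as
observed; larger inputs use the tie- and continuity-corrected normal
approximation. Effect sizes use r = |z|/√N with z recovered from the
two-sided P as Φ⁻¹(1 − P/2) — the only convention consistent with the
published (P, r) pairs at N = 32 — and Cohen labels with boundaries
assigned to the lower category (0.1 ≤ r < 0.3 small, 0.3 ≤ r ≤ 0.5
moderate, r > 0.5 large). Kernel density estimates use Scott's-rule
Gaussian kernels; per-event densities are divided by the maximum event
density (the densest event maps to exactly 1), and level contours
(0.5, 0.95) are traced on a 128² grid normalized by its own peak.

## Synthetic data

The generator is phenomenological — no hydrodynamics, channel flow
profile, or viscoelasticity is simulated. Per subpopulation the marginals
are: log-normal area (median/log-σ), beta deformation rescaled to
[0, 0.5] (observed RT-DC range, which keeps deformation < 1 exactly),
gamma-distributed excesses over 1 for area ratio and aspect ratio
(shape 2), normal brightness, gamma within-cell brightness SD, and
log-normal fluorescence maxima with a dim autofluorescence mode for
negative cells (so unstained-control thresholding is meaningful).
Contamination: debris as small (< 25 µm²) high-area-ratio fragments,
doublets as near-double-area objects with aspect > 2 — both chosen so the
published gates act non-trivially — with per-event ground-truth flags.

Default study conditions: healthy colon area median 80 µm² (log-σ 0.45),
deformation mean 0.08, area-ratio excess 0.03, brightness 110 ± 8;
disease shifts the area median ×1.3 and deformation by +0.05 and widens
the spreads (log-σ ×1.25, deformation concentration ×0.6, area-ratio
excess ×1.7), reproducing the qualitative tumour orderings (larger, more
deformed, rougher, more heterogeneous cells). No quantitative per-cell
effect sizes are published for these tissues — only sample-level
statistics — so the defaults are fixed at values that a practitioner
would call a clearly pathological but not caricatured shift, and are not
revisited. Matched-pair cohorts default to 16 pairs with 2,000–10,000
events per sample (bracketing the ~1,500-cell minimum for stable
classification) and add per-sample biological variability: one
log-normal factor (CV 10%) on all area medians and one Gaussian offset
(SD 0.012) on deformation means per sample, mimicking animal-to-animal
spread — without it, replicate samples would differ only by counting
noise and paired tests would be degenerate.

Rendered frames rasterize a superellipse |x/a|ᵖ + |y/b|ᵖ = 1 (p = 2:
ellipse) with a linear centre-to-edge intensity ramp on a noisy
background; the ground truth is the analytic boundary polygon (512
vertices; geometry from a 4,096-vertex densification) whose area and
perimeter match the closed forms (πab, Ramanujan) to < 10⁻⁵ relative.

What passing tests show — and what they do not: the synthetic cohorts
validate the pipeline's correctness, determinism, type-I control (blind
accuracy at chance when healthy ≡ disease) and power under the stated
effect sizes. They do not validate the biological effect sizes
themselves, multi-population tissue complexity, instrument drift, or
optical artefacts; conclusions about real biopsies require the deposited
DCOR datasets.

## Numerical choices and problem sizes

- Seeds: every stochastic routine takes an explicit seed; cohort
  generation derives per-sample sub-seeds from one `numpy` Generator, so
  results are bit-reproducible.
- The acceptance script and the Monte-Carlo tests use 50–200 cohort
  replicates, 8-pair cohorts at 1,000–3,000 events for null calibration
  and 16-pair cohorts at the default 2,000–10,000 events for power —
  sizes chosen so each analysis completes in seconds to a few minutes on
  one CPU while keeping Monte-Carlo error well below the asserted margins.
- Degenerate inputs raise typed errors (`GeometryError` for zero-area
  contours, `DegenerateInputError` for all-zero paired differences or
  zero-variance correlations, `SchemaError` for missing columns) rather
  than propagating NaNs.
- CSV I/O uses `%.17g` formatting and round-trip float parsing so
  numeric payloads survive text serialization bit-exactly.

## Known limitations

- Single-subpopulation defaults for healthy/tumour colon; real tissue
  has many physical clusters (the generator supports arbitrary mixtures,
  but the presets keep one for interpretability).
- The transfer-colitis effect-size pairs published for N = 14 cannot be
  reproduced from the printed sample size alone (back-calculation is
  inconsistent), so they are not used as checks here.
- No compensation/spillover handling for multi-channel fluorescence; no
  post-acquisition texture features; no survival or grading endpoints.
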