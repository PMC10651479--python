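# tissuedc

Label-free diagnostics of solid-tissue biopsies from real-time deformability
cytometry (RT-DC). After a biopsy is mechanically dissociated into a
single-cell suspension and pushed through a microfluidic constriction, the
instrument records a brightfield image of every cell. `tissuedc` implements
the downstream analysis that turns those per-cell images into a tissue-level
diagnosis:

1. **Per-cell physical phenotypes** — cross-sectional area *A* (µm²),
   deformation *d* = 1 − 2√(πA_hull)/P_hull (zero for a circle), aspect
   ratio (bounding-box extents along/across the flow axis, max/min),
   area ratio A_hull/A_contour (≥ 1, large for ragged debris-like
   outlines), and brightness mean/SD inside the contour — extracted by
   segmenting each frame and tracing the cell contour.
2. **Gating** — events below 25 µm², with area ratio > 1.1 or aspect
   ratio > 2 are debris; small cells (< 60 µm²) additionally require area
   ratio ≤ 1.05. Doublets (aspect > 2, large) are flagged separately, and
   fluorescence positivity (e.g. CD45 for leukocytes) is thresholded on an
   unstained control from the same tissue.
3. **Sample featurization** — cells are split into cross-sectional-area
   categories (mouse colon: 60–90, 80–120, 120–400 µm², which overlap by
   design) and each category is summarized by the mean, median and sample
   SD of the selected features, giving a fixed-length vector per biopsy
   (3 × 4 × 3 = 36 parameters for the mouse-colon scheme).
4. **Classification** — feature vectors are min-max scaled to [0, 1] on the
   training cohort, projected onto the first two principal components
   (SVD of the mean-centred matrix), and a logistic regression on
   (PC1, PC2) separates healthy from tumour samples. Blind samples pass
   through the frozen scaler/PCA/regression without refitting.
5. **Group statistics** — Mann–Whitney U (independent groups, e.g. colitis
   vs. control) and Wilcoxon signed-rank (matched tumour/healthy pairs)
   with exact small-sample P values, effect sizes r = |z|/√N with
   z = Φ⁻¹(1 − P/2), Pearson correlation, and max-normalized kernel
   density estimates for scatter colouring with 0.5/0.95 level contours.

A synthetic-data generator (`tissuedc.synthetic`) emulates healthy and
tumour cohorts, inflamed colon with a stiff CD45⁺ leukocyte subpopulation,
debris/doublet contamination, and rasterized single-cell frames with
analytic ground-truth contours, so the whole pipeline is testable without
instrument data. The study's real datasets live on the Deformability
Cytometry Open Repository (DCOR, <https://dcor.mpl.mpg.de/organization/soteriou-kubankova>)
and can be analysed with the same functions after loading with
`tissuedc.io.read_events` (the HDF5 `events`-group container layout).

## Worked example

```python
import tissuedc as t

# a matched cohort: 16 tumour/healthy pairs, 2,000-10,000 cells per sample
cohort = t.sample_cohort(t.CohortSpec(n_pairs=16), seed=3)

cfg = t.preset("mouse_colon")          # 3 size bins x 4 features x 3 stats
vecs = []
for rec in cohort:
    kept, labels = t.apply_debris_gates(rec.events)
    vecs.append(t.summarize_sample(kept, cfg, sample_id=rec.sample_id,
                                   label=rec.condition))
matrix, labels = t.assemble_matrix(vecs)
print(matrix.shape)                    # (32, 36)

model = t.fit_pipeline(matrix, labels, seed=0)
print((model.explained_variance_ratio * 100).round(1))   # [88.5  4.7]

blind = t.sample_cohort(t.CohortSpec(n_pairs=1), seed=99)
bvecs = []
for rec in blind:
    kept, _ = t.apply_debris_gates(rec.events)
    bvecs.append(t.summarize_sample(kept, cfg, sample_id=rec.sample_id))
bmatrix, _ = t.assemble_matrix(bvecs)
for p in t.predict_samples(model, bmatrix):
    print(p.sample_id, round(p.probability, 3), p.label)
# s000_healthy 0.03 healthy
# s000_disease 0.968 disease
```

The explained-variance fractions say how much of the cohort's parameter
variance the two retained components carry; the probability is the
logistic-regression confidence that a sample is tumour (cutoff 0.5).

The same pipeline is scriptable from a shell:

```sh
tissuedc simulate --pairs 16 --seed 3 --out cohort/
tissuedc featurize --manifest cohort/manifest.csv --preset mouse_colon --out features.csv
tissuedc train    --features features.csv --out model.json
tissuedc predict  --model model.json --features features.csv --out predictions.csv
tissuedc stats    --features features.csv --out wilcoxon.csv
```

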