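# panctex

Quantitative CT texture analysis for pancreatic ductal adenocarcinoma
(PDAC) and its association with overall survival.

Resected PDAC has dismal survival and few pre-operative prognostic markers.
Contrast-enhanced CT is acquired routinely, so second-order texture
statistics of the tumor — how heterogeneous the lesion looks at the pixel
scale — are candidate imaging biomarkers. `panctex` implements that
analysis end to end for researchers working with CT volumes, ROI masks and
a survival table:

1. **Image layer** — NIfTI volumes and binary tumor/normal-pancreas masks;
   voxels with HU < −10 or > 500 are excluded (fat, fluid, stents); the
   analysis uses the largest cross-section of each ROI.
2. **Texture layer** — HU quantized to G grey levels (default 64 over
   [−10, 500]), a symmetric grey-level co-occurrence matrix (GLCM) at
   offset δ = 1 pixel pooled over the four 2D orientations, restricted to
   in-mask pixel pairs. From the normalized matrix C:

   - uniformity  Σ C²ᵢⱼ
   - entropy   Σ Cᵢⱼ ln Cᵢⱼ  (kept non-positive, as defined)
   - dissimilarity Σ Cᵢⱼ |i−j|
   - inverse difference normalized Σ Cᵢⱼ / (1 + |i−j|²/G²)
   - correlation  Σ (i−μₓ)(j−μᵧ) Cᵢⱼ / (σₓσᵧ)

   plus mean in-mask HU and cross-sectional area (mm²).
3. **Statistical layer** — tumor vs normal Mann–Whitney rank test;
   univariate Cox proportional hazards per feature with the Wald χ²(1)
   test (Breslow ties, Newton–Raphson on the partial likelihood); ROC/AUC
   against the median-overall-survival dichotomy with the Youden operating
   point and Hanley–McNeil 95% CI; median-split Kaplan–Meier with log-rank.
   Subjects who die within 3 months of surgery are excluded.
4. **Synthetic cohort** — phantom volumes (darker, textured tumor ≈ 57 HU
   next to normal parenchyma ≈ 71 HU, moving-average correlated noise) and
   survival times whose log-hazard is linear in the standardized value of
   a chosen texture feature, so the whole pipeline is testable without
   clinical data.

## Worked example

```python
import panctex as px

# simulate a 30-subject cohort in which dissimilarity drives the hazard
table = px.generate_cohort(px.PhantomSpec(), px.CohortSpec(n=30, effect_beta=0.8, seed=3))
results = px.TextureSurvivalModel.from_dataframe(table).fit()
print(results.summary())
```

prints (abbreviated):

```
Tumor vs normal tissue (Mann–Whitney rank test)
----------------------------------------------------------------------
       feature  tumor_median  normal_median   U         p
mean_intensity          56.9           71.2   0 2.872e-11
 dissimilarity         1.056         0.5687 756 6.065e-06
...
Univariate Cox regression (Wald test, chi-square 1 df)
----------------------------------------------------------------------
       feature      B      SE  wald         p  n  n_events
 dissimilarity   2.74  0.7459 13.49 0.0002393 30        20
```

The tumor reads out darker than normal pancreas (median 56.9 vs 71.2 HU,
rank-sum p ≈ 3e-11), and the feature that was wired to the hazard —
dissimilarity — comes out with a positive log-hazard coefficient and a
small Wald p, while undriven features mostly do not. `results.plot_km()`
draws the median-split Kaplan–Meier curves and `results.roc` holds the
AUC/threshold table.

The same analysis runs from the shell:

```bash
panctex simulate --out cohort/ --n 30 --seed 3
panctex extract  --manifest cohort/manifest.csv --out features.csv
panctex analyze  --features features.csv --survival cohort/survival.csv --out report/
# or everything at once from a YAML config:
panctex run --config config.yaml --seed 3 --out report/
```

`report/` contains `features.csv`, the three analysis tables
(`table3_comparison.csv`, `table4_cox.csv`, `table5_roc.csv`),
`summary.txt` and a Kaplan–Meier PNG per significant feature.

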