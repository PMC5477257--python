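# Methods

## Image substrate and admissibility filtering

Volumes are 3D grids of Hounsfield units with the slice axis first and
voxel spacing (dz, dy, dx) in mm; masks are congruent binary grids labelled
tumor or normal. Before any texture computation, in-mask voxels with
HU < −10 or HU > 500 are removed. The band is inclusive at both ends
(−10 and 500 survive): the rule as stated removes values strictly outside
it, and the low cut matters scientifically — fat interdigitates between
pancreatic lobules and at contour margins, and a handful of −100 HU voxels
would dominate any co-occurrence statistic with a texture signal unrelated
to the tumor. The high cut removes stents and dense fluid. The filter is
idempotent and always yields a subset of the input mask; an ROI that
filters to empty is a per-subject extraction error, logged and skipped at
the cohort level.

Features are computed on the single slice with the largest filtered
cross-section (ties broken toward the lower slice index), reported
together with its area (pixel count × dy × dx, mm²) and the mean in-mask
HU on that slice. This "largest cross-section" convention yields one value
per feature per subject; it forgoes volumetric averaging by design, and
3D co-occurrence offsets are out of scope.

## Quantization and the co-occurrence matrix

HU is quantized into G equal-width bins over [lo, hi]:
level = ⌊G·(HU−lo)/(hi−lo)⌋ clamped to G−1 at HU = hi. G is not dictated
by the source feature definitions, so it is a parameter; the default
G = 64 over the filter band [−10, 500] (bin width ≈ 8 HU) keeps the G×G
matrix dense at ROI cross-sections of 10²–10³ pixels while not collapsing
genuine HU contrast. Out-of-mask pixels carry a sentinel level.

The GLCM accumulates pair counts P_ij at interpixel distance δ = 1 over
the four 2D orientations (0°, 45°, 90°, 135°), pooled into a single
matrix before normalization; a pair contributes only when both pixels are
in-mask. By default each pair is counted in both (i,j) and (j,i), so C is
exactly symmetric. Pooling counts (rather than averaging one matrix per
orientation) is the rotation-robust convention consistent with reporting
one value per feature; the orientation set and symmetry are configurable.
C = P/ΣP, so ΣC = 1 whenever at least one admissible pair exists; zero
admissible pairs raise a degenerate-GLCM error rather than emitting NaN.

The five statistics are computed exactly as defined in the README.
Numerical conventions:

- entropy uses the natural logarithm and keeps the sign of Σ C ln C
  (non-positive; 0 iff a single nonzero cell). Standard texture libraries
  negate it; here the defining sum is reported as-is. Published cohort
  values of this quantity at ×10⁻³ scale are not reproducible from this
  formula at any plausible G; no rescaling is attempted.
- "inverse difference normalized" uses the denominator 1 + |i−j|²/G² —
  formally the *moment* variant of the normalized inverse difference. The
  label follows the source feature set; the formula is implemented as
  printed.
- correlation is undefined when σₓσᵧ = 0 (constant in-mask texture); it is
  reported as NaN with a logged warning, and such subjects are dropped
  pairwise from downstream statistics for that feature only.

## Statistical layer

**Tumor vs normal comparison.** Mann–Whitney rank test per feature, ties
sharing mid-ranks; exact enumeration when the pooled sample has ≤ 12
observations without ties, otherwise the normal approximation with
tie-corrected variance (no continuity correction). Medians and IQRs are
reported per tissue.

**Survival association.** One univariate Cox proportional-hazards fit per
feature — the cohort sizes this analysis targets (tens of subjects) cannot
identify a multivariate model. The partial likelihood uses the Breslow tie
approximation by default (Efron available); Newton–Raphson on the score
with tolerance 1e-8, the covariate centred and scaled internally and the
estimate mapped back, which leaves β exact. Standard errors come from the
observed information; the Wald statistic is (β/SE)² against χ²(1) and the
invariant holds by construction. A constant covariate raises a
non-identifiability error; a monotone likelihood (covariate perfectly
ordering the event times) raises a divergence error rather than returning
a huge pseudo-estimate.

**ROC.** Survival is dichotomized at the cohort median time (label 1 iff
time ≥ median, midpoint convention for even n); a fixed-horizon rule in
months is available in config. The choice of dichotomy is a modelling
decision, not an estimate — the median split mirrors the 15/15 structure
of the motivating 30-subject design. AUC is the rank statistic
U/(n₁·n₀) with tied pairs counted ½, oriented so AUC ≥ 0.5 with the flip
recorded; the operating threshold maximizes Youden's J with ties resolved
toward the lower threshold; the 95% CI is Hanley–McNeil (deterministic,
matches legacy statistical software rather than a bootstrap); the p-value
tests AUC = 0.5 through the equivalent Mann–Whitney statistic.

**Kaplan–Meier.** Product-limit curves for the feature-≥-median vs
below-median groups with the log-rank χ²(1) test, via lifelines. Subjects
dying within 3 months of surgery are excluded from all survival analyses
(post-operative mortality is not tumor biology); censored-before-3-months
subjects are retained.

No multiple-testing correction is applied across the seven features; the
reports print raw p-values with that caveat, matching the exploratory
biomarker setting.

## Synthetic cohort

The generator exists so that every stage is testable without clinical
data; it emulates the *statistical* structure of a PDAC cohort, not its
anatomy.

- **Phantom.** 8 slices of 48×48 pixels at (5.0, 0.625, 0.625) mm — a
  5 mm reconstruction interval with sub-millimetre in-plane pixels. The
  tumor is an ellipsoid (per-slice ellipses shrinking away from the
  mid-slice) of ≈ 2 cm² maximal cross-section; the normal-parenchyma ROI
  is a disjoint ellipse on the same slices. Mean HU: tumor 57, normal 71,
  the portal-venous contrast of PDAC. Texture is white Gaussian noise
  smoothed per slice by a uniform moving-average of half-width ℓ pixels
  and rescaled to the target SD — a dependency-light construction whose
  GLCM read-out is empirically monotone in both SD (rougher) and ℓ
  (smoother). Defaults: tumor SD 12 HU, normal SD 8 HU, ℓ = 1.5 px. HU is
  clipped into the admissibility band with the clipped count logged.
- **Cohort.** Per subject, a tumor noise SD ~ U(4, 24) HU and a tumor
  radius scale ~ U(0.6, 1.4) are drawn (heterogeneity and size axes),
  the phantom rendered, and features extracted through the real texture
  module. The driven feature (default dissimilarity) is standardized
  across the cohort to z; survival time is Exponential with rate
  λ₀·exp(β·z) — hazard linear in the *standardized* feature so β is
  comparable across features of wildly different raw scales — with
  λ₀ = 1/31 per month (mean uncensored survival 31 months) and
  administrative censoring ~ U(0, 120) months (≈ 25% censored). Phantom
  rendering and survival draws use separate child streams of one master
  seed; a cohort is bit-for-bit reproducible from (spec, seed).

What passing synthetic tests do **not** show: phantoms have no organ
boundaries, partial-volume effects, contrast-timing variation, scanner
noise spectra or contouring error, so effect sizes recovered here say
nothing about clinical effect sizes — only that the estimators are
implemented correctly and calibrated under their own assumptions.

## Verification strategy and problem sizes

- The masked GLCM is checked for exact count equality against a naive
  double-loop pair enumerator on hundreds of random grids (≤ 8×8, G ≤ 8,
  every orientation subset), plus closed-form cases (constant image,
  two-level checkerboard) at 1e-12.
- The Cox solver is checked against a scalar maximization of an
  explicitly coded Breslow partial likelihood, against lifelines (Efron
  ties) on tied data, for sign equivariance, and for parameter recovery
  (β = 0.8/SD, n = 300, 100 seeds, coverage ≥ 90% at ±2·SE).
- The Mann–Whitney p is checked against a 10⁵-draw permutation null; the
  AUC≡U/(n₁n₀) identity is asserted on random tied data; log-rank and
  Mann–Whitney rejection rates under permutation nulls at n = 15/15 must
  fall inside the 99% binomial band around α = 0.05 (2000 reps).
- End-to-end runs at n = 100 must be byte-identical across reruns.

Tests and the acceptance script deliberately use small phantoms
(4 slices of 32×32, tumor radii (10, 7) px) for the many-seed simulations;
this is a package choice to keep Monte-Carlo suites desk-scale, and the
monotonicity/recovery properties being tested are size-independent.

## Known limitations

- 2D, single-slice, single-offset texture only; no GLRLM/GLSZM/wavelet
  families and no IBSI-compliance claims.
- The ROC dichotomy treats censored-before-median subjects by their
  observed time; with heavy censoring a time-dependent ROC would be more
  appropriate and is out of scope.
- The Hanley–McNeil interval is asymptotic and can be optimistic at very
  small n; it is reported because it is the legacy-package convention.
- DICOM series ingestion, registration and RTSTRUCT contours are not
  handled; convert to NIfTI upstream.
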