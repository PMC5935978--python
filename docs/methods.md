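# Methods

This note documents the models, numerical conventions and design choices
behind `nodulequant`, in the spirit of a statistical-software methods
appendix. It states what the code computes and what the synthetic data do and
do not emulate; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## 1. The measurement model

A CT volume is a 3D grid of integer Hounsfield units (HU) with physical voxel
spacing. A nodule mask `M` is a single 26-connected set of voxels. The
quantification reduces the masked voxels to:

* **mean CT value** — arithmetic mean HU over `M` (with min/max);
* **HU histogram** — counts over half-open, integer-aligned 1-HU bins
  `[v, v+1)`; the counts always sum to `|M|`;
* **component proportions** — with thresholds `t_GGO < t_Sc`,
  `GGOc% = |{HU ≤ t_GGO}|/|M|·100` and `Sc% = |{HU ≥ t_Sc}|/|M|·100`.
  Voxels strictly between the thresholds belong to neither component, so
  `GGOc% + Sc% ≤ 100`.

Because HU are integers and the conventional thresholds are half-integral
(−411.5, −189.5), a voxel value can never tie with a threshold; the
open/closed convention is immaterial and the tests assert this invariance.
A histogram bin that would straddle a threshold (only possible with bins
wider than 1 HU) raises rather than silently splitting mass.

### Segmentation

Clinical measurements of this kind use proprietary auto-contour software
with a manual editing loop. Here segmentation is seeded region growing:
voxels with HU above a floor (default −750 HU), 26-connected to the seed,
within a physical radius cap of the seed, followed by morphological closing
(ball, radius 1 voxel). `edit_mask` applies include/exclude voxel sets and
re-validates connectivity, reproducing the inspect-and-edit contract.
Border contact is detected on the grown region (before closing, which erodes
at the array boundary) and flagged as a truncation warning. Exclusion of
juxta-vascular structures is heuristic — radius cap plus editing — and is
not claimed equivalent to any commercial tool.

The −750 HU default floor sits between aerated lung (about −870 HU) and the
ground-glass distribution (mean −553 HU), excluding ~97% of lung voxels
while keeping ~97% of GGO voxels at the default noise levels; on blur-free
phantoms the grown mask achieves Dice ≥ 0.90 against the true support.

### Threshold derivation

The ROC uses the Mann–Whitney AUC (ties counted ½) over all cutpoints, which
are midpoints between adjacent distinct predictor values flanked by
sentinels. The "optimal" cutoff maximizes the Youden index
J = sensitivity + specificity − 1; ties are broken toward higher
specificity. The predictor is the per-tumor mean CT value: it is the only
tumor-level statistic step 1 produces. The GGOc threshold takes pGGO as the
positive class with *low* values positive; the Sc threshold takes SN as
positive with *high* values positive. On simulated appearance cohorts
(58/159/158 tumors per class at the class HU models below) the derived
cutoffs land between the generating class means and vary by only a few tens
of HU across seeds, bracketing the conventional −411.5 / −189.5 HU values.

## 2. The phantom generator

The generator exists because no patient volumes are publicly available; it
produces volumes whose composition is known exactly, so recovery can be
tested rather than assumed.

**Geometry.** The nodule is a sphere (the degenerate ellipsoid) of diameter
≤ 3 cm centered in a lung-background cube with a 6 mm margin, at isotropic
voxel spacing (default 1.0 mm, matching thin-slice reconstruction). The
solid component is a single central focus: nodule voxels are ranked by
distance from the center and the nearest `round(n·(1 − lepidic_fraction))`
are labeled solid. This pins the solid voxel fraction to within one voxel of
the requested value — an analytically sized inner sphere would carry a
voxelization error of a few percent at these radii — while preserving the
central-invasive-focus geometry seen histologically in lepidic-predominant
tumors.

**HU model.** Per-voxel HU are i.i.d. Gaussian per component, clamped to
[−1024, 100] HU (clamping, not resampling: deterministic, and the clipped
mass is negligible at the defaults). Defaults are the whole-class appearance
statistics: GGO −553.38 ± 101.1 HU, solid −104.24 ± 93.05 HU. Lung
background is −870 ± 50 HU — a typical aerated-parenchyma value chosen here,
since the source tables do not report one. Air pockets (vacuole < 5 mm,
cyst/cavity ≥ 5 mm, the radiological convention) are spheres set to
−1000 HU. An optional vessel is a 1.5 mm-radius cylinder at +50 ± 20 HU
tangent to the nodule, exercising the segmentation radius cap. Partial
volume is modeled as isotropic Gaussian blur of the HU field (σ default
0.5 mm) applied last; voxels are then rounded to int16. The returned mask is
the pre-blur nodule support.

**Ground truth.** `solid_voxel_fraction` counts solid over tissue
(GGO + solid) voxels before blur; the lepidic percentage is its complement
rounded to the pathologist's 5% recording grid. Histology follows the
invasive-focus size rule: AIS for no focus, MIA for a focus ≤ 5 mm,
invasive otherwise; the focus diameter defaults to the solid component's
physical diameter. Appearance classes use configurable bands on the solid
fraction: pGGO below 5%, SN above 95%, PSN between. The 5%/95% band edges
are a convention — trace components below visual detectability stay in the
pure classes — since no published mapping from visual class to exact solid
fraction exists.

**Determinism.** All randomness flows from one `numpy` Generator seeded by
the spec; identical specs give bit-identical volumes, masks and records.

### Cohort simulation

Cohort records emulate the published group margins (283 invasive vs 92
non-invasive): continuous covariates are truncated normals on their legal
supports (size 2.04 ± 0.55 vs 1.55 ± 0.51 cm on (0, 3]; GGOc 14 ± 17 vs
44 ± 29%; Sc 56 ± 30 vs 14 ± 21% on [0, 100]; SUV_max 3.75 ± 2.85 vs
1.54 ± 2.41, present for the PET/CT fraction 147/375). Categorical
covariates use **exact largest-remainder counts** per level with seeded
permutation rather than i.i.d. draws: the study conditions are the printed
contingency margins (e.g. exactly 1 of 92 non-invasive tumors with
necrosis), and multinomial sampling at such probabilities frequently yields
zero-count cells and spuriously separated logistic fits that the real cohort
does not exhibit.

Choices the data do not dictate, made once here: GGOc and Sc are drawn
independently (their per-record sum may exceed 100%, impossible for a real
histogram but harmless for covariate margins); the lepidic percentage is
generated as `clip((GGOc + (100 − Sc))/2 + ε, 0, 100)` with ε ~ N(0, 15)
rounded to the 5% grid, which couples it positively to GGOc and negatively
to Sc at magnitudes comparable to the observed rank correlations; the
per-tumor mean HU is drawn from the appearance-class model after the
appearance is derived from the drawn Sc proportion.

**What the phantoms do not emulate:** reconstruction-kernel texture and
correlated noise, scanner-to-scanner HU calibration differences, contrast
enhancement kinetics, irregular/spiculated shapes, bronchovascular anatomy,
and any real joint distribution of the covariates beyond the couplings
above. Passing recovery tests therefore shows the *measurement machinery* is
correct under the stated noise model, not that the published thresholds are
optimal for real scanners.

## 3. Statistical machinery

* **t tests** — pooled-variance and Welch variants from summary statistics
  (scipy), signed as second group minus first. The source tables are
  internally inconsistent about the variant: the appearance-class rows match
  the pooled t exactly, the proportion rows match Welch, and the size row
  matches neither on rounded inputs; both variants are exposed and
  `reproduce_tables` reports the pooled form for the rows it matches.
* **Categorical tests** — Pearson χ² without continuity correction (required
  to match the printed statistics) with Fisher's exact (two-sided
  hypergeometric enumeration) alongside for 2×2 tables; expected counts
  below 5 trigger the exact report.
* **Spearman** — tie-aware mid-rank correlation (scipy), p via the t
  approximation.
* **Logistic regression** — maximum likelihood via statsmodels' Newton
  (IRLS) with Wald SEs; odds-ratio CIs are exp(β ± 1.96·SE). Complete or
  quasi-complete separation is detected (non-convergence or non-finite SEs)
  and raised as a flagged error — `analyze_cohort` records it and continues,
  since small simulated cohorts can legitimately separate. Rank-deficient
  designs raise with the collinear columns named. Proportions enter the
  model on the 0–1 scale (configurable), so the Sc odds ratio reads "0%
  versus 100%".
* **DeLong comparison** — correlated-AUC Z test from per-subject structural
  components (placement values), implemented here and verified against an
  explicit double-loop oracle; identical predictors give Z = 0 exactly and
  swapping predictors flips the sign.
* **Combined predictor** — the fitted linear predictor of the size + Sc
  logistic model, the standard score for "combination" ROC curves; on
  separation the fallback score is the sum of standardized predictors.
* **Agreement** — Bland–Altman limits use the 1.96 multiplier (the "95%
  limits" convention) with sample SD; ICC is ICC(2,1) — two-way random
  effects, absolute agreement, single measures — computed from ANOVA mean
  squares with the McGraw–Wong F-based CI, cross-checked against pingouin.
  ICC(2,1) matches the design: both raters rate all tumors and systematic
  rater offsets should count against agreement. Exactly identical columns
  return ICC = 1 exactly (bypassing ANOVA round-off), which the replay
  harness uses: re-running the measurement with the same seed must give
  perfect agreement.

## 4. Problem sizes and tolerances

Test and acceptance runs use sizes chosen to make the checks sharp yet
quick: recovery uses 100 blur-free phantoms of 1–2 cm (≈ 500–4200 nodule
voxels each) with component SDs of 30 HU — "well separated" relative to the
thresholds, so the expected misclassified mass is < 0.1% and the ±2
percentage-point recovery bound tests geometry and counting rather than
noise overlap. Wald-interval calibration runs 500 logistic replicates at
n = 400 with β = (−0.5, 0.8, 1.0), checking the focal slope's 95% CI covers
its true value in 93–97% of replicates. The AUC-ordering check simulates 100
full-size cohorts (283/92) and requires Sc to out-predict size in ≥ 95 of
them. Calibration assertions on means use 3-standard-error bands plus the
0.5 HU integer-rounding slack.

## 5. Known limitations

* The derived HU thresholds depend on the assumed class HU models; the
  package brackets but cannot certify the conventional −411.5/−189.5 HU
  values, because no patient-level data exist to re-derive them.
* Whether the original threshold derivation used tumor-level or voxel-level
  predictors is unstated; tumor mean CT is the default here as the only
  quantity step 1 produces.
* Segmentation is a generic region grower; its Dice guarantee is
  demonstrated on phantoms only.
* The cohort simulator matches first and second moments and category
  margins, not the real joint distribution; odds ratios fitted to simulated
  cohorts are expected to differ in magnitude from the published ones even
  when directions and AUC orderings agree.
* No survival analysis is provided, and SUV_max participates only as a
  univariate covariate (it is missing for tumors without PET/CT and is
  excluded from the multivariable model).
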