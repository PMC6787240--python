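# Methods

## Problem and scope

The package quantifies paired, co-registered FET-PET SUV and ADC volumes of
post-treatment glioma patients and classifies each lesion as recurrent
tumour (REC) or post-treatment related effect (PTRE). Because no patient
images ship with the package, every empirical claim is made on *synthetic*
cohorts produced by the phantom module; the statistics and segmentation
operators are additionally verified against independent brute-force oracles.
Volumes are assumed co-registered (hybrid PET/MR acquisition); no
registration, attenuation correction, SUV scaling from raw activity, or
contrast-enhancement analysis is performed.

## Segmentation model

The lesion VOI is the 80 % isocontour (IC80) of the hottest lesion:
voxels with SUV ≥ 0.8 × the component maximum, 26-connected, containing the
component peak. Choices the underlying procedure leaves open, fixed here:

- **Connectivity** is 26-neighbour in 3-D — the permissive standard for
  hot-spot masks; an 18- or 6-connected variant would only split components
  at diagonal necks, which the smooth phantom lesions do not produce.
- **Seeding** is automatic: the global in-mask maximum (the operator-guided
  step of semi-automatic delineation is replaced by
  `select_prominent_lesion`, which ranks components by SUVmax, then voxel
  volume, then distance to an optional reference point; residual ties break
  on the lowest peak-index triple for reproducibility).
- **Local re-thresholding**: the selected component is re-cut at 0.8 × *its
  own* maximum, so a dimmer secondary lesion still carries a true 80 %
  isocontour of its own peak.
- **Margin adaptation** on the ADC grid removes voxels with
  ADC ≥ 2400 × 10⁻⁶ mm²/s (free water ≈ 3000; tumour values are far below)
  or inside a user exclusion mask; removal of > 50 % of the VOI raises an
  error, flagging a mis-placed VOI rather than silently averaging CSF.
- **Background**: a contralateral disk of the same in-plane voxel count as
  the VOI's cross-section on the representative slice (highest mean uptake),
  centred at the mirror image of the in-slice centroid across the
  mid-sagittal plane x = 0. A disk is used because the guideline's crescent
  ROI is not reconstructible from a published description; area-matching
  ("similar size") is exact to one voxel. The same mirrored region,
  transferred to the ADC grid, supplies the ADC background, so both
  modalities are normalised at one anatomical locus. Whether the original
  operators mirrored geometrically or placed ROIs on anatomy is unknown;
  mirroring is the reproducible choice.

## Phantom model

Each phantom is an ellipsoidal "brain" (semi-axes 55 × 65 × 45 mm) on a
64 × 64 × 48 grid at 2 × 2 × 2.5 mm (anisotropic, PET-like; small enough for
seconds-scale rendering), zero outside the brain, with:

- Gaussian voxel noise on background SUV (σ = 0.03, ≈ 3 % of background —
  plausible for OSEM-smoothed PET) and ADC (σ = 40 × 10⁻⁶ mm²/s, ≈ 5 %);
- two CSF spheres (fixed ADC 3000 × 10⁻⁶ mm²/s, SUV 0.2 — free-water
  diffusivity and near-absent amino-acid uptake; the values are plausible
  physiology, set by design, and noiseless so the CSF signature is
  unambiguous);
- one focal lesion: radial profile `bg + A·exp(−(r/σ)^p / 2)` with
  σ = 6 mm, amplitude `A = peak − bg`, centred on a voxel centre strictly
  lateral to the midline. The **hot core** — where the noise-free SUV
  reaches 80 % of the peak — is filled with i.i.d. Gaussian ADC
  (per-patient mean drawn from the group calibration; within-lesion
  σ = 100 × 10⁻⁶ mm²/s), then dilated by one voxel: the diffusion signature
  extends marginally beyond the metabolic isocontour so that noise-induced
  jitter of the segmented boundary stays inside it. Without the margin,
  boundary jitter admits a thin shell of background-ADC voxels and biases
  pipeline ADCmean ≈ 3 % low relative to the generating truth.

The lesion centre default coincides with a voxel centre; an off-grid peak
makes the sampled voxel maximum underestimate the analytic peak by several
percent, biasing TBRmax and mis-sizing the isocontour.

### Group calibrations

Published summaries report group means and the standard error of the mean
difference (MD ± SE) at group sizes 32 (REC) / 10 (PTRE). Under a
pooled-variance two-sample model the implied between-patient SD is
`sd = md_se / √(1/n₁ + 1/n₂)`, shared by both groups:

| quantity | REC mean | PTRE mean | MD SE | derived SD |
|---|---|---|---|---|
| hot-core ADCmean (10⁻⁶ mm²/s) | 1313 | 1029 | 91 | 251.2 |
| TBRmax | 3.18 | 2.09 | 0.45 | 1.242 |

Backgrounds: SUV 0.94 / 1.11, ADC 768 / 755 (REC / PTRE). Per-group SDs are
not published, so the pooled derivation is an assumption of this package,
not a reported fact.

**Truncated TBR sampling.** TBRmax must exceed 1/0.8 = 1.25 for an 80 %
isocontour to be a compact hot spot, so draws are truncated below at 1.4
(margin keeps the maximal hot-core radius ≈ 10 mm, inside the declared
13 mm lesion extent). At SD 1.242 a naive truncation would inflate the PTRE
mean from 2.09 to ≈ 2.6, so the normal's location is solved (Brent on the
truncated-normal mean) such that the *truncated* mean equals the printed
group mean. The drawn TBR sets the lesion peak via
`peak = TBR × bg_suv_mean`.

**Profile exponent.** For a pure Gaussian (p = 2) the continuum
mean-to-max SUV ratio over the IC80 region is ≈ 0.874 regardless of σ,
above the published TBR80mean/TBRmax ratio 2.75/3.18 = 0.865. The exponent
is therefore a calibration parameter, solved once so the continuum ratio at
TBR 3.18 equals 0.865 (p = 1.6344). With this single constant the PTRE-arm
expectation works out to 1.80 — matching the published PTRE TBR80mean
without being fitted to it.

### What the phantoms do not emulate

No anatomy (tissue atlases, grey/white contrast), no PET point-spread or
partial-volume effects, no Rician/ADC-fit noise structure, no motion, no
resection cavities, single lesion by default (a secondary-lesion option
exists to exercise prominent-lesion selection). Passing calibration
recovery therefore validates the *pipeline arithmetic* end-to-end — that
segmentation, transfer, margin trimming and background normalisation
recover the distributions the generator encodes — not the clinical
separability of the two diagnoses on real images, and not the published
patient-level AUCs or operating points, which require the original cohort.

## Statistics

- **t-test**: Student's pooled-variance form (consistent with the
  mean ± SE reporting convention); Welch behind a flag.
- **AUC**: normalised Mann–Whitney statistic, ties counted ½. SE by
  DeLong's structural components (algebraically identical to the grouped
  delete-one jackknife, which the tests exploit as an oracle). 95 % CI on
  the logit scale (boundary-safe; collapses to a point at AUC ∈ {0, 1});
  p-value vs 0.5 by normal approximation. The CI method of the source
  analysis is unstated; logit is this package's choice.
- **Youden**: exhaustive scan over midpoints of consecutive unique scores
  plus the two extreme cutoffs, classification "score > cutoff"; ties in J
  break toward higher specificity.
- **Step-wise rule**: REC iff TBRmax > 2 **or** ADCmean > 1254 (strict
  inequalities, matching the published "> threshold" operating point).
- **Bivariate ROC**: all pairs of candidate thresholds under the OR rule;
  the upper-left staircase (left-continuous step function) through the
  Pareto-optimal attainable points, integrated exactly. For a tie-free
  single marker this reproduces the rank AUC; with exact cross-class ties
  the ½-tie rank convention can exceed the staircase value. SE by
  stratified subject bootstrap (default 2000 resamples, seeded). How a
  binary two-threshold rule yielded a published full ROC curve is
  ambiguous; the envelope is this package's documented construction, and
  the published bivariate AUC of 0.90 is not treated as reproducible.
- Undefined predictive values (zero denominator) are reported as NaN,
  never as 0.

## Calibration-recovery evaluation

`scripts/acceptance.py` and the acceptance tests simulate 200 phantoms per
group (fixed seed), run the full pipeline, and compare group means of
ADCmean, TBRmax, rADCmean, TBR80mean and the two between-group differences
against the calibration targets within 3 Monte-Carlo SEs. The REC and PTRE
arms share one per-patient seed stream (common random numbers): marginal
distributions are unchanged, while difference estimates shed the
between-patient sampling noise — standard variance reduction for paired
contrasts. rADCmean gets 2 % extra slack because the published value is a
ratio of group means while the pipeline averages per-patient ratios.
Problem sizes (200 per group, 64 × 64 × 48 grids) keep the whole evaluation
under a minute on one CPU.

## Known limitations

- The derived between-patient SDs inherit the pooled-variance assumption;
  if the real groups had unequal variances the phantom dispersions are
  mis-calibrated (the means are not).
- TBRmax recovery carries a small (+2–3 %) upward bias from taking a
  maximum over noisy voxels; it is well inside the 3-SE acceptance band at
  the default noise level but would grow with noisier backgrounds.
- The mirrored background assumes lateralised lesions and a symmetric
  brain mask; midline lesions are rejected rather than analysed.
- External NIfTI data must be RAS-oriented with the mid-sagittal plane at
  x = 0 (or a `midline_world_x` override) and ADC already in 10⁻⁶ mm²/s.
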