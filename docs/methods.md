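# Methods

`habitatsurv` implements a tumor-habitat imaging pipeline for glioblastoma
survival classification: unsupervised intensity clustering of co-registered
multimodal MRI into physiologic habitats, radiomic feature extraction per
habitat, random-forest recursive feature elimination (RF-RFE), and a
gradient-boosted-trees classifier evaluated by repeated leave-one-out
cross-validation (LOOCV). Because the clinical cohort this pipeline targets
is not publicly available, the package ships a first-class synthetic phantom
generator whose defaults encode the published cohort statistics, so every
stage is testable end to end against known ground truth.

## Phantom cohort model

### Geometry

Each subject lives on a 64×64×64 grid of 1 mm isotropic voxels (configurable).
The tumor is the set of `N` voxels closest to a hemispheric center under an
anisotropically weighted Euclidean distance (weights drawn per subject), i.e.
an ellipsoid with mild random eccentricity whose voxel count is exact by
construction. Radial ordering of the tumor voxels defines the compartments:
a necrotic core, a contrast-enhancing (CE) shell around it, and a
non-enhancing outer margin. Sub-habitats (the high-MD blob inside necrosis,
the high-perfusion blob inside CE, low-MD extensions into CE and the margin)
are placed by seeded region growing from a random interior voxel of their
parent compartment, restarting from a fresh seed if a component is exhausted;
this guarantees the exact drawn voxel count and connected, blobby shapes.
Normal-appearing white matter (NAWM) is a fixed ellipsoid in the
contralateral hemisphere, disjoint from the tumor by construction.

### Volume distributions

The published per-group habitat volumes (mean ± SD, cm³) are marginal
summaries:

| group | En | Nec | LMD-LrCBV | HMD-LrCBV | En-HrCBV | tumor |
|---|---|---|---|---|---|---|
| short | 1.51±0.45 | 2.07±0.59 | 3.20±0.73 | 1.01±0.49 | 0.65±0.37 | 6.02±5.1 |
| long  | 1.26±0.41 | 2.64±0.65 | 2.47±0.88 | 1.95±0.77 | 0.42±0.23 | 6.07±5.4 |

Treated as independent normals these are mutually infeasible under the
containment constraints (a tumor drawn at 2 cm³ cannot hold 5 cm³ of
habitats; the tumor SD alone implies ~12% negative draws). The generator
therefore draws:

- **En, Nec** — truncated normals (floor 0.1 cm³; the truncation mass is
  negligible at the default parameters).
- **HMD-LrCBV and En-HrCBV** — as Beta-distributed *fractions* of their
  parent compartment (Nec and En respectively). The Beta moments are solved
  so that the product fraction×parent has exactly the published marginal mean
  and SD; containment then holds surely, with no rejection step that would
  bias the marginal.
- **LMD-LrCBV** — a plain normal (floor 0.05 cm³). The necrotic remainder
  (Nec minus the HMD blob) is always low-MD tissue; if the drawn LMD-LrCBV
  total is smaller than that remainder, the surplus necrotic low-MD voxels
  are made *high*-perfusion (a necrotic hyperperfused focus — necrotic rCBV
  is reported as non-zero in this disease), otherwise the remaining LMD-LrCBV
  mass extends into CE∩LrCBV and then the non-enhancing margin. Either way
  the LMD ∩ LrCBV volume equals the drawn value exactly, preserving the
  marginal without rejection.
- **Whole tumor** — a lognormal moment-matched to the published mean/SD
  (volumes are positive and right-skewed), redrawn until it exceeds
  En + Nec + the non-enhancing low-MD mass plus a 0.2 cm³ margin and fits the
  grid (≈30 cm³ cap, <1% of draws).

**Consequence (known limitation):** the five habitat volumes calibrate to the
published rows within 3 standard errors over 500 subjects per group (tested),
but the *whole-tumor* volume is conditioned on containing its habitats and is
therefore biased upward (≈9–10 cm³ versus the printed 6 cm³). The printed
whole-tumor marginal cannot be met jointly with the habitat marginals under
any independent-draw scheme; we keep the habitat volumes exact because the
group comparisons and acceptance checks are defined on them, and the paper
itself reports no group difference in whole-tumor volume.

### Intensities

Each map is piecewise-constant plus noise: every tissue region (background,
brain, NAWM, and the map-relevant tumor regions) has a group-level plateau
mean, a between-subject SD (the subject's plateau is drawn once per map and
region), and an additive voxel-noise SD. Plateaus are ordered so the k-means
naming conventions hold (post-contrast T1w: necrotic < non-enhancing < CE;
MD: LMD < HMD; CBV: LrCBV < HrCBV), and the group contrasts point in the
reported effect directions — short-term survivors have lower MD in the
low-diffusivity habitat (0.70 vs 0.90 µm²/ms), higher relative CBV in the
low-perfusion habitat (1.60 vs 1.10 after NAWM normalization), higher T2w
signal, and higher CBF. The magnitudes are package defaults, not published
values (the source reports directions and significance only); they are chosen
so that plateau separations are ≥6 voxel-noise SDs (making segmentation
reliable but imperfect) and group gaps are 2–4 between-subject SDs, i.e. a
clearly separable cohort. NAWM CBV has unit mean so rCBV normalization is
well defined; survival class is group membership directly (the study
dichotomizes survival at 15 months; simulating survival times would add
nothing the classifier sees).

**What a green test establishes:** that the pipeline recovers known
structure — exact habitat geometry, calibrated volumes, separable intensity
contrasts. It does not establish clinical effect sizes: real cohorts carry
partial-volume voxels, registration error, spatially correlated noise,
non-ellipsoidal lesions and much weaker, correlated group contrasts, none of
which the phantom emulates.

## Habitat segmentation

Each map is clustered independently over the within-tumor voxels
(scalar k-means): post-contrast T1w with k=3, MD with k=2, and NAWM-normalized
rCBV with k=2. The solver is Lloyd's algorithm from k-means++ starts
(n_init=10, tolerance 1e-6 on the maximum center shift, ≤300 iterations);
because every 1-D Lloyd fixed point assigns sort-contiguous clusters, each
restart is then polished by a Hartigan-style single-point boundary pass
(strictly inertia-decreasing), which removes the rare residual local minima —
with the polish, restarted Lloyd matches an exact dynamic-programming 1-D
k-means oracle on 100/100 seeded mixture trials (tested). Cluster *names*
bind to ascending centers, never to raw labels, so relabeling cannot change
the output. Clustering is pooled 3-D by default; a slicewise mode clusters
each axial slice separately (per-slice center ordering harmonizes labels,
thin slices fall back to the pooled centers).

The ten-ROI catalog is derived by intersection: the three T1c compartments,
LMD/HMD, LrCBV, LMD∩LrCBV within CE, LMD∩LrCBV within necrosis, HMD∩LrCBV
within necrosis, and En-HrCBV defined as CE minus LrCBV (the source names
this ROI without defining it; CE ∩ HrCBV is the only intersection consistent
with its name). Empty intersections are retained with a warning and produce
missing features rather than aborting.

## Radiomic features

Per ROI and per map (T1c, T2w, MD, FA, rCBV, CBF) the extractor computes
four histogram statistics — mean, sample SD (n−1), moment skewness
g1 = m3/m2^1.5 and excess kurtosis g2 = m4/m2² − 3 (missing when n < 3 or
m2 = 0) — and four GLCM texture features. GLCM conventions (the source is
silent on all of them): ROI intensities quantized to 32 equal-width levels
over the ROI's own range; co-occurrences accumulated over all axial slices
and four in-plane unit offsets ((0,1),(1,0),(1,1),(1,−1)), both pixels
in-ROI, counted symmetrically and pooled into a single matrix normalized to
sum 1; contrast Σp(i,j)(i−j)², correlation with a zero-variance → 0 policy,
energy Σp², homogeneity Σp/(1+|i−j|). Energy is included as the fourth
texture feature because the printed 480-feature total requires
10 ROIs × 6 maps × 8 features; no enumeration reaches 480 with only three
GLCM features. Relative volumes go to a separate volume report (used for the
group-volume analog) and are not appended to the classifier table, keeping
the 480 count.

Cohort fusion imputes missing cells by the per-column median, drops
all-missing columns with a warning, and z-scores each column. During
cross-validation, imputation and standardization statistics are refit on
each training fold and applied to the held-out subject, so the saved
cohort-level table is for inspection while the evaluator always uses the raw
values.

## Learners

All estimators are written from scratch on a single CART kernel (numba-JIT;
split search over sorted feature values with midpoint thresholds, ties to the
lowest feature index). For 0/1 targets the variance-reduction split is
identical to the Gini split (node SSE = n·p(1−p)), so one kernel serves
regression and classification.

- **Random forest** — bootstrap resamples, ⌊√p⌋ random candidate features
  per node, trees grown to purity (min_leaf 1), majority vote; importances
  are total impurity decrease per feature, normalized to sum 1.
- **RF-RFE** — refit the forest (200 trees) on the surviving features, drop
  the ⌈0.1·remaining⌉ lowest-importance features (≥1, never past the
  target), repeat until exactly 60 remain; importance ties break by feature
  name.
- **Gradient boosting** — f0 is the prevalence log-odds; each stage fits a
  depth-limited tree to the residuals y − σ(F) on a seeded subsample and
  replaces each leaf value by the Newton step Σr / Σp(1−p) (denominator
  floored at 1e-12, leaf values clipped to |γ| ≤ 10), then F += ν·tree.
  Training log-loss is recorded per stage and is non-increasing at
  subsample 1 (tested).
- **Hyperparameters** — a stratified inner-CV tuner over a
  ν ∈ {0.05,0.1,0.3} × depth ∈ {1,2,3} × M ∈ {50,100,200} ×
  subsample ∈ {0.8,1.0} grid is provided (ties prefer the smaller model).
  The *default* evaluation pipeline uses fixed values (ν=0.1, depth 2,
  M=100, subsample 1.0) rather than tuning inside every LOOCV fold of every
  trial: the full grid there costs ~50× the entire evaluation budget and, on
  the cleanly separable phantom cohort, changes nothing the acceptance
  checks measure. Tuning can be switched on in the evaluation config.

The positive class is short-term survival (the clinically urgent class);
macro-averaged precision/recall/F1 are reported alongside.

## Evaluation

LOOCV holds out each subject once; preprocessing, feature selection and the
classifier are refit on the remaining n−1 (leakage-safe default). The
`paper_faithful` switch instead selects features once on the full cohort
before the folds — the common optimistic shortcut — and logs a leakage
warning. Repeated trials reseed the stochastic components (RFE forests,
boosting subsampling); the folds themselves are deterministic. The panel:
accuracy, precision, recall, F1, Mann–Whitney AUC (ties ½) on the pooled
held-out probabilities, and the Matthews correlation coefficient;
zero-denominator metrics report 0 with a warning, never raise mid-report.
The ROC is swept over the unique pooled probabilities of the first trial and
its trapezoidal area equals the pair-counting AUC exactly (tested).

A caution documented by the null tests: pooled LOOCV probabilities are
pessimistically biased on null data (the training prevalence anti-correlates
with the held-out label), so single-dataset null AUC sits *below* 0.5;
averaging over fresh label permutations recovers 0.5. The permutation-null
test therefore permutes labels afresh each trial.

## Determinism and numerics

Every stage seed derives from one global seed via `numpy` generators; derived
seeds stay below 2³¹. Identical configuration and seed reproduce every
artifact bit-for-bit: gzipped NIfTI members are written with a zeroed mtime
and no filename field, CSV floats use fixed formats, and JSON keys are
sorted. Degenerate inputs are handled explicitly: constant ROIs quantize to
level 1 and give contrast 0 / energy 1 / correlation 0; clustering a map
with fewer distinct values than k raises an error naming the map; empty ROIs
yield missing features; a single-class training fold predicts the majority
class with a logged warning.

## Known limitations

- Whole-tumor volume is conditionally biased upward (see above); all five
  habitat volumes calibrate exactly.
- The phantom's texture is noise-only, so GLCM features carry essentially no
  group signal by construction; classification signal lives in the
  intensity and volume structure. Real-data texture effects are outside the
  phantom's vocabulary.
- Intensity magnitudes are package conventions chosen once for a separable
  cohort; accuracy numbers on phantoms are an upper bound on what the same
  pipeline would achieve clinically.
- No partial-volume modeling, registration error, bias fields, or
  non-ellipsoidal lesion shapes.
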