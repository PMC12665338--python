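# Methods

This note documents the models, parameters and numerical choices behind
`dtiabv`, a reanalysis pipeline for combined diffusion-tensor imaging (DTI)
and atlas-based volumetry (ABV) group studies along the bvFTD / ALS-FTD
spectrum, exercised end to end on synthetic phantom cohorts.

## The phantom generator

Patient MRI from such studies is not redistributable, so every downstream
stage is validated against a generator whose ground truth is known exactly.

**Anatomy.** All subjects share one grid (default 48×48×48 voxels at 2 mm
isotropic), standing in for a cohort already normalized to a stereotaxic
standard space; spatial normalization itself is out of scope.  The brain is
an ellipsoid (default semi-axes 42/40/40 mm).  White-matter tracts are tubes
around polyline or circular-arc centerlines (five named tracts by default:
an uncinate-like hook, a callosal-genu arc crossing the midline, superior
and inferior longitudinal association tracts, and a corticospinal-like
projection tract; tube radius 8 mm, axes laid out more than two radii
apart so the tract masks are disjoint).  Gray-matter structures are
ellipsoids with atlas label ids (two frontal lobes, a temporal lobe, two
caudate-like nuclei, an amygdala-like nucleus).

**Tensors.** Tract voxels carry axially symmetric tensors with the principal
axis along the local centerline tangent and eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s (FA ≈ 0.80); the remaining brain is isotropic at
the same mean diffusivity (MD = 0.767×10⁻³ mm²/s), so MD is spatially
uniform and FA effects are purely anisotropy effects.  A target FA `f` at
fixed MD is realized through the closed form
λ₁ = MD(1+2δ), λ₂ = λ₃ = MD(1−δ) with δ = f/√(3−2f²), valid for any
f ∈ [0, 1); effect injection is therefore exact, not iterative.

**Signal.** DWI follows the single-tensor model S = S₀ exp(−b gᵀDg) with a
31-direction Fibonacci half-sphere scheme at b = 1000 s/mm² plus one b = 0
volume (S₀ = 1000).  Noise is Rician — the magnitude of two independent
Gaussian channels — with σ relative to S₀ (default 0.02, i.e. b0 SNR 50, a
typical 3T value).  Signal is simulated only inside the head; outside voxels
carry no signal and are masked invalid by the fit, which also keeps large
multi-seed simulations affordable.

**Injected effects.** Group effects are fractional FA reductions per tract
(injected by shrinking λ₁ toward MD, preserving MD) and fractional volume
losses per structure (injected by depth-ranked erosion of the structure
mask with a fractional weight at the cut, placed on cumulative GM mass, so
any target percentage is hit exactly even on a coarse grid; eroded GM is
converted to CSF, leaving the intracranial total untouched).  Additional
knobs: an additive per-site FA offset, a linear FA-versus-age slope,
severity coupling (a patient's effect scales with its clinical score
relative to the group mean), and extended effects at the longitudinal
follow-up timepoint, emulating antero-posterior progression.

**Between-subject variability.**  Rician noise alone leaves almost no
between-subject variance in tract-averaged or ICV-standardized quantities,
which would make group z-scores absurdly large.  Two variability fields fix
this: a per-subject multiplicative FA scale (SD 0.04 by default, persistent
across timepoints) and an independent per-structure volume jitter (SD 0.03,
segmentation-style).  Both default to zero in a bare `EffectSpec`, so
noiseless calibration checks remain exact.

**Default effect magnitudes.**  The generator's defaults (FA reductions of
6–14% over affected tracts, volume losses of 10–36%, the ALS-FTD pattern
additionally involving the projection tract, site offset +0.02, age slope
−0.001 FA/yr) were chosen so that pooled-SD z-scores on the default noise
level land in the −1 to −3 range that cross-sectional bvFTD/ALS-FTD tables
report.  They approximate that regime; they are not fitted to any
particular published cell.

**Determinism.**  One master seed; demographics draw from stream
`[seed, 0]`, each subject/timepoint row from `[seed, row_index, stream]`
(stream 1 = signal noise, 2 = volume jitter).  Identical inputs give
bit-identical outputs, independent of generation order.  Noiseless signals
and erosion weights are cached across rows sharing identical effect
parameters; caching cannot affect results, only speed.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: motion, eddy-current and susceptibility artifacts,
crossing fibers (one tensor per voxel by construction), spatially varying
MD, real segmentation error structure, registration error, and
non-Gaussian age effects.  Conclusions about the *pipeline's* statistics
transfer; conclusions about scanner physics do not.

## Tensor estimation and scalar maps

The estimator is ordinary (unweighted) log-linear least squares on
ln S = ln S₀ − b gᵀDg, the minimal standard choice; weighted and robust
(RESTORE-type) variants are deliberately out of scope.  A boolean
per-direction exclusion flag stands in for quality control of corrupted
gradient directions.  FA and MD use the eigenvalue closed forms; negative
eigenvalues (a noise artifact) are clamped to zero for the scalar maps
while the voxel stays valid — this keeps FA within [0, 1] without
discarding data.  The averaged control dataset used for group tractography
is the component-wise (Euclidean) mean of control tensor fields with the
intersected validity mask; log-Euclidean averaging would be the main
alternative but the pipeline's reference procedure does not specify it,
and for the SNRs involved the difference is far below the tracking
tolerances.  Tensor-space (rather than raw-signal) averaging is likewise a
choice made here and flagged as such.

## Preprocessing

Fixed order: smooth → age-correct → harmonize.

* **Smoothing**: separable Gaussian, specified in mm FWHM
  (σ = FWHM/(2√(2 ln 2))), default 8 mm; nearest-edge boundary replication.
* **Age correction**: per site, a voxel-wise linear regression of the map on
  age fitted on that site's controls only; every subject is shifted to a
  common reference age (default: mean control age).  A site with all
  control ages equal is an error, not a silent skip.
* **Site harmonization**: a control-anchored voxel-wise linear first-order
  map taking each site's control mean onto the pooled control mean.  The
  default is offset-only, Δ(v) = pooled(v) − site(v) — the minimal model
  consistent with a first-order correction, and exactly testable: after
  correction the site control means are equal by construction.  An optional
  multiplicative (gain) term matching control SDs is provided but off by
  default.  No empirical-Bayes (ComBat-style) pooling.

## Whole-brain voxel-wise statistics (WBSS)

Two-group comparisons use Welch's t (unequal variances,
Welch–Satterthwaite df), two-sided; clinical-score correlations use Pearson
r with the sign kept in the report.  The analysis mask is the set of voxels
with smoothed control-mean FA > 0.2 — attaching the 0.2 threshold to a
control-derived mask keeps the mask independent of patient groups.
Correction is Benjamini–Hochberg FDR at q = 0.05 over in-mask voxels
*followed by* a cluster-extent threshold of 256 mm³ (FDR-then-extent;
26-neighbor connectivity, configurable).  Zero-variance voxels get t = 0,
p = 1 by convention and are logged.  Spherical peak ROIs are placed at each
cluster peak and its mirror across the grid midsagittal plane, clipped to
the analysis mask, deduplicated on the midline.  Permutation-based cluster
inference (TFCE etc.) is a non-goal.

## Tractography and TFAS

Deterministic fixed-step Euler integration along the trilinearly
interpolated principal eigenvector, bidirectional from every seed voxel
center; step 0.5× the smallest voxel size, termination at FA < 0.2, turning
angle > 40°, or grid exit; the eigenvector sign follows the previous
direction.  These integrator constants are this package's own defaults, all
configurable.  A tract of interest is the set of streamlines with at least
one point in the seed mask and one in the target mask (a symmetric
criterion), plus the union of voxels they traverse.  TFAS is the arithmetic
mean of a subject's FA over the TOI voxels, counting only voxels with
subject FA > 0.2 (voxel-set averaging is invariant to streamline
multiplicity).  TFAS uses age/site-corrected but **unsmoothed** maps:
smoothing belongs to the voxel-wise pathway, and tract averaging already
suppresses noise; using smoothed maps would dilute tract-mean effects at
the boundary.  Group tables report Welch p (BH-corrected across tracts) and
the pooled-SD z-score, z = (m₁−m₂)/s_p with the Bessel-weighted pooled SD
s_p = √(((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2)).

## Atlas-based volumetry (ABV)

Structure volume = Σ probability × mask × voxel volume over the chosen
compartment; ICV = total GM+WM+CSF.  Volumes are standardized linearly to
the mean control ICV (idempotent on a standardized table).  Cross-sectional
group tests fit a per-structure two-level linear model
`volume ~ group + age` (age as covariate), pairwise per group pair rather
than a three-group omnibus, BH-corrected across structures; a constant
response yields p = 1 by convention, a rank-deficient design is an error
naming the collinear columns.  Longitudinal change is reported as percent
change of the **group means**, 100·(FU − BL)/BL to two decimals, signed
(an increase is positive); the per-subject paired mean change is reported
alongside.  Clinical correlation is a partial Pearson correlation with age
partialled out by double residualization (identical to the recursive
formula; cross-checked in tests against an independent implementation).

## Random forest

The fixed scikit-learn model: 100 trees, Gini criterion, depth 4,
min-split 2, min-leaf 1, `max_features="sqrt"`, bootstrap on, fixed random
state.  Subjects (21 TOI mean-FA + 24 SOI volume features in the full
design; 5 + 6 in the default phantom) are split 80/20 stratified by class;
the training portion is evaluated by stratified 5-fold cross-validation,
reporting fold-averaged accuracy, sensitivity and specificity with the
patient class positive (bvFTD positive in the bvFTD-vs-ALS-FTD task).
Because it is ambiguous whether published summary metrics of such designs
are CV-fold averages or held-out-validation values, both are computed and
labeled.  Feature elimination removes the single least Gini-important
feature per round — the most conservative reading of "removing the least
important features" — refits with CV, and keeps the reduced set only while
fold-averaged accuracy does not drop below the previous value minus a
tolerance (default 0); it stops at 2 features at the latest and emits a
per-round audit trail.  Missing feature values drop the subject with a log
entry; nothing is imputed silently.

One property worth noting: with `max_features="sqrt"`, duplicating a
feature does *not* split its importance evenly — the duplicate pair enjoys
higher candidate availability and its combined importance grows.  The
even-split identity holds when all features are candidates at every split,
and the test suite checks it in that regime.

## Pipeline and problem sizes

A single YAML config drives all stages (phantom → tensors → preprocess →
WBSS/TOI/ABV → forest); all thresholds above are config keys with the
defaults stated.  Every output file is SHA-256-hashed into a provenance
manifest; identical configs yield identical manifests.

Validation problem sizes are chosen for a single-CPU reanalysis: the
type-I-control and harmonization experiments run 100 cohorts of 10
subjects per arm (the acceptance script uses 60 per quantity), effect
recovery uses 40 subjects per arm with a 15% FA reduction, volumetry
recovery uses noise-free generation where the erosion construction is
exact, and the classifier checks use 20 repetitions.  The demo pipeline
configuration runs three groups of 8–10 subjects with 3–4 longitudinal
follow-ups in well under a minute.

## Known limitations

* Single-tensor model only; no crossing-fiber, kurtosis or NODDI variants.
* The harmonization null check is partly self-fulfilling for the offset
  model (site control means are equalized by construction); its value is in
  verifying the full path and the gain variant.
* Printed z-scores in the reference group tables of this literature are not
  generally reproducible from printed (rounded) means and SDs under the
  Bessel-weighted pooled-SD formula; this package reports that formula and
  does not attempt to reverse-engineer variants.
* The 21 real-anatomy TOIs and 24 SOIs of a full study enter as
  configuration data (seed/target definitions, atlas masks), not code; the
  default phantom carries a reduced but structurally faithful set.
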