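# Methods

This note documents the models and procedures the package implements,
the assumptions behind the synthetic cohort generator, and the choices
made where the design was genuinely open. Notation: `s` is a latent
neglect severity in [0, 1], CoC the centre of cancellation, z-scores
are standardized against the control patients' acute scores.

## Behavioural scoring

**Centre of cancellation.** For a sheet with targets at normalized
horizontal positions `x_i ∈ [−1, +1]` (0 = centre, +1 = right edge)
and marked set M, `CoC = mean_{i∈M} x_i`. Positive CoC = rightward
bias = left neglect, matching the cutoff direction (letters > 0.081,
bells > 0.083, both strict). **Zero marked targets** would leave the
mean undefined; the package returns the layout's maximum positive
position, reading a blank sheet as complete left neglect. This keeps
CoC monotone in severity at the extreme; the condition is visible to
callers via `CancellationResult.n_marked == 0`.

**Copying.** Raw score 0–8 (1 per contralateral-feature omission, 2
per wholly omitted figure, +1 for contralesional figures drawn on the
ipsilesional side, capped), pathological at ≥ 2. The raw score
(higher = worse) is standardized directly, so all three per-test
z-scores share orientation; "% correct" = 100·(1 − score/8) is
reporting-only.

**Composite z and targets.** Per-test control norms use the sample SD
(ddof = 1) of ≥ 2 controls; zero variance is an explicit error, not a
silent division. The composite is the mean of the available per-test
z-scores; patients with incomplete batteries are averaged over what
exists and flagged (`TestBattery.is_complete`) rather than dropped —
diagnosis itself only needs one test, so incomplete batteries are part
of the design. The three chronicity targets are the chronic composite
z, the difference acute − chronic (positive = improvement), and the
effectiveness of recovery, per test
`ER = 100 · (acute − chronic) / (acute − floor)` clipped to [0, 100]
and averaged over the tests whose acute score exceeds the floor.
**Floors default to 0** for all three tests: this reproduces the
stated endpoints exactly (ER = 100 iff the deficit fully resolved,
ER = 0 iff no improvement) and makes ER invariant to rescaling a
test's score. Pathological cutoffs can be supplied as alternative
floors; with all acute scores at/below their floors ER is undefined
and raises.

**Control patients** were not re-tested in the chronic phase (their
follow-up scores are known to be at ceiling), so their chronic targets
are imputed by policy: `zero_and_full` (chronic z = 0, ER = 100 %, the
default), `carry_forward_acute` (each control keeps its own acute
composite), or `recovery_zero` (ER = 0 %). Only controls are touched.

## Lesion features

All computation happens in 0-based, row-major voxel index space on a
shared grid; the affine is carried for I/O and display only (spatial
normalization is out of scope — maps are assumed already registered).
Values must be binary; values within 1e−6 of {0, 1} are snapped (a
concession to resampling artefacts in real NIfTI files), anything else
is rejected. Volumes are `count × voxel volume / 1000` ml; the ROI
lesion size is the ml volume of lesion ∧ ROI.

The **voxel-frequency filter** keeps voxels damaged in ≥ 5 patients
and is computed **once on the whole cohort**, as the study protocol
does. This leaks cohort-level voxel frequencies across CV folds; the
leak concerns only which voxels enter the PCA, not any behavioural
outcome, but it is a known deviation from strict fold hygiene and is
recorded in every run manifest. The filter is applied independently to
the whole-brain maps and to the ROI-overlap maps.

**PCA** of each filtered patients × voxels matrix is centred, keeps at
most min(n−1, p) components, and drops numerically-zero trailing
components of rank-deficient matrices. Component blocks:

* `wb_pct_pcs` / `roi_pct_pcs`: the smallest prefix of components
  whose cumulative explained-variance ratio reaches a threshold. The
  candidate grid defaults to {0.3, 0.4, …, 0.9, 0.95}; the winning
  threshold per target and variant is the one whose block achieves the
  smallest cross-validated MSE, ties toward the smaller threshold
  (fewer components).
* `wb_fs_pcs` / `roi_fs_pcs`: the five components most strongly
  associated with the target under a filter method — absolute Pearson
  correlation (default), absolute Spearman correlation, or univariate
  F score — computed over neglect patients only. Ties break toward the
  lower component index. Three standard filters are provided because
  the choice is configurable in the protocol; which filters the
  original analysis used is not recoverable from the protocol description.

PCA, the association filter, and min-max scaling are all fit on the
full cohort, mirroring the protocol; the FS-PC blocks therefore carry
a selection advantage as single predictors (see the recovery study
below). Sex is coded F = 1, M = 0 (recorded in the feature manifest).

## Prediction engine

Epsilon-SVR with RBF kernel (libsvm via scikit-learn). **epsilon is
not specified by the protocol; the default is 0.1**, the libsvm
default the original MATLAB toolchain would have used; it is exposed
on every grid constructor. The full grid is C = 2⁻⁵ … 2¹⁵ ×
γ = 2⁻¹⁵ … 2⁵ (441 points). A reduced 5 × 5 profile samples C
exponents (−5, −1, 3, 7, 11) and γ exponents (−13, −9, −5, −1, 3):
inside the printed ranges, but avoiding the extreme-C corner where
libsvm converges orders of magnitude more slowly without winning the
inner selection at this sample size.

Nested CV: 5 outer / 4 inner folds, 10 repetitions (3 in the reduced
profile). **Folds are random partitions stratified by group**
(chronic/recovered/control). Stratification is not specified by the
protocol, but with only 12 chronic patients unstratified
folds can produce outer test folds without any evaluation patient;
the fold builder also re-randomizes (bounded) if an evaluation-empty
fold still occurs, and raises if it cannot be avoided. Training always
uses the full training folds, controls included; the inner grid search
minimizes the validation MSE pooled over the evaluation (neglect)
patients of the inner folds, ties broken toward the smallest C, then
the smallest γ (prefer the smoother model, deterministically). Each
patient is predicted exactly once per repetition; repetitions
re-randomize both outer and inner splits; final metrics (MSE mean and
SD of per-patient squared errors, cross-validated R², Pearson r) are
computed from the per-patient averaged predictions, over evaluation
patients only. Cross-validated R² may be negative. All randomness
flows from a single integer seed through `numpy.random.SeedSequence`
fan-out, so results are bit-identical across runs.

Forward selection treats each PC block as one atomic candidate (its
five components enter together), starts from the best single block,
adds the block with the largest MSE reduction, and stops on the first
iteration with no strict reduction (a tie stops). Once a location
block is selected the other location variants leave the pool, so no
model ever holds two of them. Full models contain all scalar
predictors plus one location variant each, plus one model with none
(4 variants → 5 models).

**Permutation importance.** The protocol's permutation scheme is
underdetermined, so the package uses the standard conditional
construction: shuffle the tested block's rows across patients (target
and other blocks fixed), re-run the repeated nested CV, and estimate
`p = (1 + #{null MSE ≤ observed}) / (1 + n_perm)` — the add-one
estimator with p-floor 1/(n_perm + 1). The reference n_perm is 5000;
tests and the CLI default use reduced counts with fewer CV repetitions
inside the null, which is configurable.

## Synthetic cohort generator

The real cohort cannot be shared and no generative model of it exists;
every distributional choice below is a stand-in, chosen once to match
the original cohort's summary magnitudes, and labelled synthetic in
the artefacts.

* **Groups** 12 chronic / 30 recovered / 30 control; grid 32³ at 2 mm
  voxels (desk-scale PCA, nontrivial ml arithmetic); planted spherical
  ROI of radius 6 voxels in the right hemisphere (~7.4 ml).
* **Lesions** are unions of random spheres (satellites centred inside
  the main sphere, so blobs are connected), right-lateralized, with
  log-normal volumes (σ = 0.6) whose group medians (16 / 13 / 5 ml)
  occupy the same fraction of the toy grid as the original cohort's group
  means (≈ 89 / 70 / 26 ml) do of a cerebrum.
* **Latent acute severity** is uniform per group: chronic (0.50,
  0.95), recovered (0.25, 0.95), control (0, 0.04).
* **Cancellation sheets**: n targets evenly spaced on [−1, 1];
  marking probability
  `p(x) = (1 − lapse) · [(1−s)² + (1 − (1−s)²) · sigmoid((x − (2s−1))/0.1)]`.
  The cut 2s − 1 sweeps left to right with severity; the residual
  (1−s)² decays fast enough that severe patients reach CoC ≈ 0.5–0.9,
  the magnitude severe left neglect produces on real sheets. The
  severity-independent lapse (0.02 for cancellation, 0.08 per copying
  figure) models healthy attentional slips: it gives control scores
  the small non-degenerate spread real control cohorts show (letters
  ≈ 0.00 ± 0.01, copying ≈ 95 ± 6 % correct) — without it the control
  norms would be degenerate. Lapses are position-symmetric, so they
  perturb CoC without biasing it. At severity 0 with lapse 0 every
  target is marked and CoC = 0 exactly.
* **Copying**: each figure wholly omitted with probability s², feature
  omitted with 2s(1−s) + lapse; expected score ≈ 8s.
* **Chronic outcome**: latent = w·(s, ROI-overlap fraction,
  volume/30 ml clipped) + N(0, noise_sd), clipped to [0, 1]; the
  chronic battery is then *generated* from that latent and scored
  through the real behaviour module — ground-truth z-scores are never
  written directly, so the full scoring path is exercised. Controls
  are acute-only, like the study cohort. Default weights (0.6, 0.3,
  0.1), noise_sd 0.05.
* **Guarantees by bounded rejection**: neglect patients re-draw their
  acute battery (nudging severity up) until ≥ 1 test is pathological;
  controls re-draw (halving severity) until all three are
  non-pathological. Both converge within a few tries; the default
  cohort always classifies 42 neglect / 30 control.
* **Determinism**: one integer seed fans out via `SeedSequence` into
  per-patient substreams; `deterministic_scores=True` replaces
  stochastic marking with p ≥ 0.5 thresholding for noiseless-limit
  tests (incompatible with norm fitting, since controls then have zero
  variance).

**What the generator does not emulate** — anatomy (no vasculature, no
tissue classes, no registration artefacts), CT/MR contrast,
test–retest structure within a session, group-conditional recovery
patterns (the chronic outcome follows the linear latent rule above for
*all* neglect patients, so "recovered" patients need not score normal
at follow-up), and the real cohort's effectiveness-of-recovery
distribution. Passing tests therefore show that the pipeline recovers
planted structure under realistic noise and scoring nonlinearity; they
do not certify performance on real patients.

## Validation experiments

**Selection recovery** (10 seeds): cohorts generated with weights
(0.65, 0.35, 0) — acute severity leading, ROI overlap secondary, no
volume pathway — and noise_sd 0.05; forward selection on the
chronic-severity target over the blocks {acute behaviour, age, sex,
WB size, ROI size, ROI-FS-PCs}. Checks: both generative pathways in
the selected set (≥ 8/10), final model cross-validated R² ≥ 0.5
(≥ 8/10), and acute behaviour the best *scalar* single predictor
(≥ 8/10). Two design notes. First, the chronic-z target is used for
attribution because in the z-difference target the acute pathway
partially cancels (it enters the acute composite positively and the
chronic composite negatively), diluting its single-predictor
advantage. Second, the acute-first check excludes the FS-PC block from
the comparison: its components are pre-filtered by full-cohort target
association, which advantages it as a single predictor regardless of
the generative structure — the same behaviour the original analysis
reports for its FS-PC blocks. The WB-FS-PC block is likewise omitted
from the candidate set because whole-brain maps contain the ROI
voxels, so it reads out the planted ROI pathway through a second route
and makes pathway attribution ill-posed; WB lesion size stays in as
the volume decoy.

**Null calibration** (10 seeds): weights (0, 0, 0), so the chronic
outcome is clipped noise; every single-predictor model must stay at
cross-validated R² ≤ 0.1 in ≥ 9/10 seeds. Permutation p-values under
null blocks are checked for uniformity (Kolmogorov–Smirnov, reduced
n_perm).

Problem sizes: both studies use the reduced 5 × 5 grid with 3
repetitions at n = 72, which resolves the planted-vs-null contrast
cleanly; the full 441-point, 10-repetition protocol is available
through `CVPlan` for any individual model.

## Numerical choices and degenerate inputs

* Min-max scaling: constant columns map to zeros with a degeneracy
  flag; scaling parameters are recorded per column and inverted for
  reporting predictions on the original scale.
* Metrics: R² and r require nonzero variance of the actual scores
  (error otherwise); r of exactly-constant predictions is reported as
  0 rather than NaN.
* Grid-search and threshold-search ties are broken deterministically
  (smallest C then γ; smallest threshold).
* SVR fits run with scikit-learn input validation disabled inside the
  engine (`assume_finite`); inputs are validated once at the model
  boundary (NaN checks, range checks) instead of per fit.
* Exact multiset invariance of SVR training (duplicated rows changing
  nothing) holds only while no dual variable sits at the box bound;
  the test exercises the interpolation regime.

## Known limitations

* The voxel filter, PCA, FS filter, scaling, and %-threshold search
  are fit on the full cohort (protocol-faithful); a strict
  per-training-fold mode is not implemented beyond the documentation
  of the caveat.
* The single-patient bundle refits one SVR on the whole cohort with
  inner-CV-chosen hyperparameters; its in-sample fit is not a
  generalization estimate (the nested CV is).
* Effectiveness-of-recovery magnitudes in synthetic cohorts do not
  match the original cohort's group summaries (see generator non-goals); the
  original group summary statistics are therefore compared via the
  summary-level t-tests, not via simulation.
* Linear-kernel SVR is available through `SvrSpec` only as a
  configuration escape hatch; no claims are made for it.
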