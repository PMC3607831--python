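# Methods

## The statistical model

### Seed-covariance mapping

A structural covariance network is mapped by mass-univariate regression.
For one seed and one group of n subjects, the covariate of interest is the
subject-wise mean modulated-GM value inside a 4-mm-radius sphere at a fixed
MNI coordinate (closed ball on voxel centers; membership is a pure
geometric test, independent of the analysis mask).  At every voxel v inside
the analysis mask, ordinary least squares fits

    GM_v = β0 + β1·seed + β2·gender + ε_v

and the map of interest is the one-sided (positive) t statistic of β1, with
ν = n − p residual degrees of freedom shared across voxels.  The partial
correlation reported alongside is r = t/√(t² + ν).  Estimation is exact —
one QR decomposition of the shared design, vectorized across voxels — so
results do not depend on voxel ordering or chunking; this is asserted
against a naive per-voxel normal-equations solver at 1e−8 relative
tolerance.  Gender is the only default confound, treatment-coded 0/1 with
the reference level chosen as the first level in sorted order (the seed
coefficient is invariant to this choice; tested).  Age is deliberately not
a within-group covariate; an age column is carried in the covariates table
and may be added by callers.  No global normalization or grand-mean scaling
is applied: modulated, brain-size-corrected GM images are assumed.

Voxels with exactly zero residual variance (possible in synthetic data) get
signed-infinite t, are excluded from permutation calibration, and their
count is logged.

### Group contrasts

Slope differences between two groups are mapped with the pooled interaction
model

    V_i = β0 + β1·V_j + β2·Group + β3·(V_j × Group) + ε

fit on the two groups' subjects only, with Group treatment-coded (reference
= 0) and a single pooled error variance, plus the gender confound by
default; ν = n_pooled − 4 − #confounds.  β3 is the comparison-minus-
reference slope difference and its Student t is the mapped statistic.  The
convention for contrast labels puts the chronologically younger group as
the reference, so a "Y > M" map is the one-sided test of β3 < 0
(middle-aged slope smaller).  Swapping reference and comparison exactly
negates β3 and t (tested); per-group slopes are recovered as β1 and
β1 + β3.

### Error control

The error contract is family-wise P < 0.05 with joint height and extent
thresholds.  Two height thresholds are provided:

* **Bonferroni** — one-sided Student-t quantile at 1 − α/N, N = finite
  in-mask voxels.  Closed form, conservative under the positive dependence
  that smoothing induces.
* **Permutation max-T (Freedman–Lane)** — the data are residualized
  against the nuisance block (all design columns except the tested one),
  residual rows are permuted (identity permutation always included, so the
  attainable p is bounded below by 1/n_permutations), the full model is
  refit and the map-wise maximum t recorded; the critical value is the
  empirical 1 − α quantile ("higher" interpolation).  Calibrated under
  arbitrary spatial dependence; single-voxel rejection rate verified at
  0.048–0.049 over 4000 replicates.

Random-field-theory thresholds are intentionally not implemented; the two
methods above provide the same error-control contract and are testable at
desk scale.  Extent control defaults to a fixed minimum cluster size
(extent_k, default 10 voxels in the pipeline config); a permutation
max-cluster-size alternative is available at a caller-chosen
cluster-forming threshold.  Suprathreshold voxels are labeled with
26-connectivity; cluster peaks are the maximum-t voxel with ties broken by
lowest linear index, so all tables are deterministic and sorted by
descending extent, then descending peak t.

### Extent trajectories

Network extent per (seed, group) is the count of significant positive
voxels, split by the sign of the voxel-center MNI x coordinate relative to
the seed's: ipsilateral, contralateral, and midline (x exactly 0; counted
separately and included in whole-brain, so ipsi + contra + midline =
whole-brain always holds).  Hemisphere is defined by coordinate sign, not
an anatomical mask, matching the x-flip convention for contralateral
seeds.  The qualitative trajectory tag classifies each successive
difference of whole-brain counts as down/flat/up, "flat" meaning within a
relative tolerance (default 10%, with an absolute floor of 1 voxel so
0 → 0 is flat), and names the pattern: contracting, contracting-then-flat,
V, inverted-V, flat, expanding, etc.

## The synthetic cohort generator

Subject images follow

    X_s(v) = μ(v) + Σ_k a_{g(s),k} · L_k(v) · f_{k,s}
             + γ(v)·gender_s + ε_s(v)

* **μ** — smooth anatomical baseline, a sum of Gaussian blobs (default: a
  45-mm-sd blob of amplitude 0.7 plus a smaller posterior blob), chosen so
  the default GM mask (mean > 0.1) comfortably contains all canonical seeds.
* **L_k** — network loading maps: unions of spheres, lightly smoothed
  (default 3 mm FWHM) and peak-renormalized, so suprathreshold extents have
  realistic soft edges; the ground-truth mask is the exact (unsmoothed)
  sphere union.
* **f_k** — independent standard-normal latent factors per subject; a
  network may instead reuse another network's factor (`factor_of`), which
  plants perfect covariance between a core network and a subnetwork.
* **a_{g,k}** — per-group amplitudes, the planted effect sizes.
* **γ** — gender confound map (sphere union, smoothed), added to subjects
  coded male.
* **ε** — white Gaussian noise smoothed to a given FWHM (default 6 mm) and
  rescaled by the exact discrete-kernel factor so the interior per-voxel sd
  equals noise_sigma (default 0.5).  Smoothed noise is what makes
  Bonferroni and permutation thresholds differ, so it is on by default.

Everything is drawn from one seeded generator in a fixed order, so a spec +
seed regenerates the cohort bit-identically (images are float32).  Values
may go slightly negative under noise; the linear analysis model never
assumes nonnegativity.  Default grid: 56×64×52 voxels at 2 mm, origin
(−55, −85, −33) mm — the smallest even-sized grid that contains all eight
canonical seeds and their x-flips with margin.

### The aging scenario preset

Three groups, default 80 subjects each with gender splits F50/M30, F50/M30
and F55/M25 and integer ages drawn uniformly from 18–23, 30–58 and 61–89.
Each cognitive-like system (auditory, speech, semantic, salience,
executive, default-mode) is a stable bilateral or unilateral *core*
(amplitude 1 in every group) plus an *extension* subnetwork — a remote
sphere loading on the core's factor — present only in the young group
(amplitude 1, then 0).  Extent therefore contracts sharply from young to
middle-aged and stays flat after, by construction rather than by a tuned
amplitude gradient: early designs that graded only amplitudes produced
skirt-driven extents whose group-to-group sampling fluctuation exceeded
the 10% flatness band at n = 80.  The motor system has a stable bilateral
core (amplitude 0.85) plus a midline supplementary-motor-like extension
present only in the middle-aged group, giving an inverted-V trajectory;
the visual system is a stable bilateral core (flat).  The default-mode
extension (right prefrontal sphere tied to the right angular seed,
amplitude 1.0 in Y, 0 otherwise) is the designated planted slope
difference: the noiseless young-group slope of a peak prefrontal voxel on
the seed is 1.0 and the middle-aged slope is 0.

What the generator does **not** emulate: cortical anatomy and folding,
segmentation/registration error, non-Gaussian morphometric variation,
site/scanner effects, and any correlation between age (within group) and
the planted factors.  Passing tests therefore demonstrate the statistical
machinery — exact estimation, calibrated error control, recovery of
covariance structure of the assumed form — not robustness to those
real-data complications.

## Validation experiments and problem sizes

The heavyweight checks (tests and `scripts/acceptance.py`) use desk-scale
sizes chosen up front:

* **Exactness** — 20 random instances (n 8–15, ≤10 voxels) for the
  covariance fit and 10 for the interaction fit, vs an independent
  normal-equations solver; worst relative error observed ~1e−14 (asserted
  < 1e−8).
* **Null calibration** — 200 pure-noise cohorts (20×22×20 grid at 2 mm,
  n = 20, 6-mm smoothed noise), each fit with an *independent*
  standard-normal null covariate plus the gender confound.  t values are
  pooled at eight lattice voxels ≥ 22 mm apart (noise correlation there is
  negligible, keeping the KS test's independence assumption honest) and
  compared to Student-t(17); family-wise false positives are counted at
  α = 0.05 for Bonferroni and for permutation max-T with 1000
  permutations.  A permuted *extracted* seed signal is deliberately not
  used as the null: a uniformly random permutation fixes one subject on
  average, leaking genuine seed-adjacent correlation and inflating the
  measured FWE.
* **Recovery** — 50 regenerations of the scenario (young + middle-aged
  groups, n = 80 each, default grid).  Per replicate: Jaccard overlap of
  the young group's thresholded speech-seed map with the planted truth
  (pass at ≥ 0.5), and detection of the angular-seed Y-vs-M slope
  difference with the cluster peak inside the planted prefrontal sphere.
* **Shapes** — one full three-group scenario run (240 subjects, 8 seeds ×
  3 groups) through map → threshold → count → classify; cognitive systems
  must tag contracting-then-flat, motor inverted-V, visual flat.

## Numerical and design choices

* Voxel indices are 0-based internally; every reported coordinate is MNI mm.
* NaN voxels in inputs are zeroed with a logged count; the analysis mask is
  an explicit, logged parameter (mean GM > 0.1 by default) because implicit
  masking is exactly the kind of hidden setting this pipeline avoids.
* Smoothing uses zero-padding at the grid boundary (GM maps are zero
  outside the head); per-axis sigmas support anisotropic voxels
  (σ_vox = FWHM/voxel/(2√(2 ln 2)); 12 mm on 2-mm voxels → 2.54797).
* Seed spheres partially outside the mask are still averaged over all their
  grid voxels (the ROI is geometric); a warning-level log records mask
  overlap only at the pipeline level.
* Sphere membership is a closed ball on voxel centers; connectivity is
  26-neighbor; peak and ordering tie-breaks are by lowest linear index —
  all fixed for determinism and all one-line config changes.
* Pipeline stages communicate only through files and are re-entrant;
  rerunning a stage with unchanged config reproduces outputs byte for byte.

## Known limitations

* No random-field-theory or FDR/TFCE thresholds; Bonferroni is conservative
  under strong smoothness, permutation max-T is the calibrated alternative.
* The pairwise interaction model fits the two compared groups only; there
  is no three-group omnibus test and no continuous-age model.
* Whether seed extraction should precede or follow smoothing is moot here
  (inputs are assumed already smoothed; the generator's smoothing is part
  of the data model): signals are extracted from the same images that are
  fit voxel-wise.
* Absolute extent counts depend on grid, mask and threshold settings;
  only within-run comparisons across groups (trajectories) and overlap
  with planted truth are meaningful on synthetic data.
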