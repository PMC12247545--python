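# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the known limitations.

## Spatial model

All volumes live on a shared 3D voxel lattice with a boolean brain mask
(`VolumeGrid`). The searchlight neighbourhood is the set of integer voxel
offsets within an inclusive Euclidean radius of the center
(`sphere_offsets`); radius 3 gives 123 voxels, radius 2 gives 33. At mask
or grid edges spheres are **clipped** — out-of-mask voxels are dropped
rather than the sphere discarded — so every mask voxel receives a value.
For a fixed center the surviving voxel set is identical across subjects
and conditions, so patterns remain element-wise comparable. Voxel indices
are 0-based in on-disk array order; world coordinates come from the NIfTI
affine.

Clipping has a visible consequence: where the mask is one or two voxels
thin, spheres degenerate to a handful of voxels and sphere statistics
become noisy (a 1-voxel normalised pattern distance is exactly 0 or 2).
Downstream consumers should treat values within a sphere radius of the
mask edge with caution; the peak reporter can be handed a restricted mask
for this reason.

## Decoding

Per sphere, the dataset is one pattern per subject × condition with
exactly three conditions (pain, touch, control). Classification is
one-against-one: three binary linear SVMs combined by majority vote, with
cyclic vote ties broken deterministically in favour of the first label in
the fixed order pain < touch < control. The implementation delegates to
libsvm's multiclass mode, which trains exactly those three pairwise
classifiers and applies the same first-label tie-break given our integer
label encoding; the test suite verifies equivalence against explicitly
trained pairwise SVMs.

The regularisation constant adapts to the data scale:
C = 1 / mean(‖x‖²) over the fold's training samples (option `"norm"`
divides by the mean norm instead; which of the two a given legacy toolkit
used is not recoverable, so both are exposed). Either choice makes
accuracy invariant to a common rescaling of the features, and no further
within-fold scaling is applied since the inputs are already normalised
statistics.

Cross-validation is leave-one-subject-out: train on all other subjects'
patterns, predict the held-out subject's three patterns; each sample
enters exactly one test fold, so chance is exactly 1/3 and the accuracy
denominator is 3 × n_subjects.

## Accuracy thresholding

The effective number of independent tests is taken as the number of
non-overlapping spheres fitting in the mask. Two deterministic estimators
are provided: volume division (mask voxels / sphere voxels, the default)
and cube packing (mask voxels / (2⌊r⌋+1)³). Neither is canonical — packing
counts depend on the packing rule and mask — so the resel count is always
reported alongside results and can be overridden; 725 is the documented
reference value for a 3-voxel-radius sphere in the standard adult brain
mask.

The corrected alpha α/R is converted to a critical classification count
with the exact binomial distribution. Two conventions exist and differ by
one count in the reference design:

- `inverse_cdf` (default): k* = smallest k with CDF(k) ≥ 1 − α_corr — the
  binoinv/ppf recipe; 97/210 = 46% for n = 210, p = ⅓, α_corr = 0.05/725.
- `tail`: smallest k with P(X ≥ k) ≤ α_corr, which strictly guarantees the
  tail bound (98/210 here, since P(X ≥ 97) = 7.5×10⁻⁵ marginally exceeds
  6.9×10⁻⁵).

The default follows the inverse-CDF convention because it is what the
established neuroimaging workflow computes; the map comparison is
inclusive (accuracy ≥ k*/n is significant). The tail sums are scipy's
regularised incomplete beta, exact to double precision at these tail
magnitudes; the suite cross-checks them against direct
binomial-coefficient summation.

## Pattern dissimilarity

Within each subject, sphere patterns of the three condition maps are
scaled to unit Euclidean norm and pairwise distanced:
d = √(2 − 2 cos θ) ∈ [0, 2]. Normalisation is the choice that produces
the bounded [0, 2] range (raw Euclidean distances are unbounded) and makes
the measure insensitive to overall response amplitude; it is exposed as a
flag (`normalize=False` returns raw distances). All-zero patterns are
degenerate under normalisation and map to NaN rather than 0, so inference
can exclude them. Group summaries are voxelwise NaN-aware means per
contrast; peaks are local maxima above a threshold (default 1.5, targeting
the top of the [0, 2] range) within a (2d+1)³ neighbourhood.

Correlation- or Mahalanobis-distance variants and full RDM-based analyses
are deliberate extension points, not implemented.

## Brain–behaviour inference

The per-voxel statistic is the slope t of the regression of per-subject
map values on the demeaned trait (a monotone transform of Pearson r;
|t| capped at 100 so perfect correlations stay finite, and zero-variance
voxels score 0). TFCE integrates cluster extent and height over all
thresholds with the standard volumetric exponents E = 0.5, H = 2,
connectivity 26 (6 and 18 available), and step dh = max/100 with floor
0.01 unless set explicitly; the suite checks the closed forms (isolated
voxel → v³/3, adjacent pair → √2·v³/3), monotonicity and step-halving
convergence.

The null permutes the trait vector across subjects (Fisher–Pitman; the
design has no nuisance covariates). Each permutation's TFCE volume-wide
maximum forms the null; FWE p at a voxel is
(1 + #{maxima ≥ observed TFCE}) / (n_perm + 1), reported as 1 − p. The +1
convention keeps p away from 0; when n_perm ≥ n! the n! distinct
permutations are enumerated instead and p becomes the exact tail fraction
(the suite verifies this against a brute-force enumeration oracle at
n = 5). Positive and negative correlations are separate one-sided runs
(the negative direction enhances the negated map); the full analysis is
3 contrasts × 4 subscales × 2 directions = 24 independently seeded runs.
Subjects are internally sorted into a canonical order (trait value, then
map digest) before the Monte-Carlo loop, so p-maps are exactly invariant
to consistent relabelings of the input.

n_perm defaults to 1,000 at desk scale; full-scale analyses conventionally
use 30,000. The same machinery accepts raw per-subject condition or
contrast maps, which provides the analogous univariate analysis with
identical inference.

## Synthetic cohorts

Each subject × condition volume is i.i.d. Gaussian noise smoothed with a
Gaussian kernel (FWHM in voxels, default 2), rescaled to unit variance and
scaled by `noise_sd` — matching the first-order statistical structure of
smoothed z-maps, whose spatial autocorrelation is what makes searchlight
and TFCE behaviour realistic. Signal regions add `amplitude ×` a
per-condition template to the noise; templates default to mutually
orthogonal unit-norm random vectors, so the designed normalised distance
between conditions approaches √2 at high SNR (per-voxel SNR is
amplitude/(√n_roi · noise_sd)).

Trait coupling is contrast-selective: for a coupled contrast, the two
conditions receive ±½·s_i·u where u is a fixed unit direction orthogonal
to the templates and s_i = base_separation + slope·(trait_i − mean) +
N(0, subject_sd). The third condition is untouched, so only the coupled
contrast's separation tracks the trait; at negligible noise the raw
in-region distance equals |s_i|, giving the closed-form design correlation
r = slope·sd_trait / √(slope²·sd_trait² + subject_sd²) that the suite
checks by simulation. Trait subscales are truncated normals on the 0–30
scale of six 0–5 items (defaults FS 17±5, EC 20±4.5, PT 19±4.5, PD 12±5,
plausible adult sum scores); subscales are generated independently —
item-level structure and inter-subscale correlations are not modelled.

The generator does not emulate anatomy, registration error, physiological
artifacts, hemodynamics or inter-subject spatial misalignment. Passing
tests therefore show that the *analysis machinery* is correct and
calibrated under idealised spatial structure, not that any given real
dataset satisfies its assumptions.

The default desk-scale grid is 24³ (tests mostly use 14³–20³ with an
ellipsoid mask, a few hundred to ~2,600 mask voxels, 12–20 subjects and
300–500 permutations); the full 91×109×91 standard grid is supported but
not a default, and sizes were chosen so a complete end-to-end run stays
comfortable on a single CPU.

## Known limitations

- **The binomial null is anti-conservative for cross-validated accuracy.**
  Leave-one-subject-out predictions are positively dependent (folds share
  all but one subject; a fold's three predictions share one classifier),
  so null accuracies are over-dispersed relative to Binomial(3n, ⅓): on
  pure-noise cohorts with 20 subjects the package's own simulations show
  per-sphere accuracy sd ≈ 0.07–0.08 versus the binomial 0.061, and a
  ~9% rate of exceeding the nominal 5% binomial critical accuracy (pooled
  over 16 cohorts). The thresholding stage reproduces the conventional
  binomial recipe faithfully; treat its nominal alpha as approximate, and
  prefer the permutation machinery when exact error control matters.
- Sphere statistics within one radius of a thin mask edge are degenerate
  (see above).
- The resel count is estimator-dependent; report it with any thresholded
  map.
- The permutation scheme assumes exchangeable subjects (no nuisance
  covariates, no exchangeability blocks); variance smoothing and
  cluster-extent alternatives are out of scope.
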