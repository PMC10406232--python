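# Methods

## The decoding model

The central object is a linear ε-insensitive support vector regression from a
depth-limited set of cortical-surface voxels to a target time series. For a
run with T time points, the feature vector **x**(t) collects the preprocessed
BOLD intensities of the F surface voxels (or of F volumetric subdivisions;
see below) at time t, and the label y(t) is the target series, z-scored per
run so that the insensitivity tube ε = 0.1 has the same meaning for every
target. Training solves

    min_{w, b}  0.5 ‖w‖² + C Σ_t max(0, |y(t) − w·x(t) − b| − ε)

with a linear kernel. Full-surface models use C = 100, ε = 0.1; the sparse
subdivision models use the SVM-light default C = (mean_t ‖x(t)‖²)⁻¹,
recomputed per fit, with ε unchanged. The solver is libsvm's deterministic
SMO (via scikit-learn's `SVR`) at duality-gap tolerance 1e-6 and an iteration
cap of 10⁶; the cap exists because labels far outside the feature span — a
situation the surrogate fits below create on purpose — can otherwise make SMO
arbitrarily slow at large C. No internal feature scaling is applied in voxel
mode, mirroring the fMRI-SVR tooling convention; subdivision means already
share an intensity scale. An optional mean-centering flag is deliberately
absent: centering is the preprocessing's job.

Accuracy is estimated by split-half cross-validation: a subject's two runs
alternately serve as training and testing data, each direction scoring the
Pearson correlation r between the predicted and observed test labels, and the
two are combined by arithmetic mean (a Fisher-z combination is available as
`decoder.mean_r_fisher`). r is invariant to positive affine maps of the
prediction, so the z-scoring of y affects nothing downstream of training.
A zero-variance prediction is recorded as r = 0 with a flag rather than NaN.

## Surface masks

The surface is defined morphologically, not by surface reconstruction: a
depth-limited shell simulates what a depth-attenuated scalp recording can
see. From the whole-brain mask A, the subsurface mask is

    B = { v ∈ A : d(v, background) > m },

where d is the center-to-center Euclidean distance to the nearest background
voxel, scaled per axis by the voxel size, computed after padding the volume
with one zero plane on every face so a brain touching the field of view still
has a surface. The strict inequality puts a voxel at exactly m mm into the
surface, reading "within m mm" as the closed ball. m defaults to 10 mm, a
depth conservatively reachable by MEG and fNIRS; the depth sweep runs 5–20 mm
and the surface mask is non-decreasing in m by construction. A Chebyshev
(per-axis) metric is available behind a flag for the anisotropic reading of
"within m mm in any direction"; it requires isotropic voxels because the
chamfer transform used to compute it has no anisotropic sampling.

The inferior-exclusion mask C is the union of all one-voxel downward (−z)
translations of B — by default iterated over the full z extent, so C contains
every voxel strictly below a B voxel within its own (x, y) column. The final
mask is A ∧ ¬B ∧ ¬C: the top and lateral shell without the inferior surface,
which scalp probes cannot reach. The depth convention (0-based indices,
voxel-center positions, axis 2 inferior→superior) is fixed in `core_io`, and
oblique NIfTI affines are rejected rather than resampled, since resampling is
registration territory and out of scope.

## Preprocessing

Each run is cleaned voxelwise by OLS against a nuisance design: the WM and
CSF mean series, the six motion parameters, and a polynomial drift basis of
degree 0..4. The drift block is a discrete Gram–Schmidt (QR)
orthonormalization of {1, t, …, t⁴} on [−1, 1] — the span is identical to raw
powers, so residuals match a raw-power regression exactly, but the design is
perfectly conditioned. Columns that do not increase the design's rank are
dropped with a warning (a constant motion trace, for example, is redundant
with the degree-0 column, which is seeded first so the nuisance trace is the
one flagged). Residuals are orthogonal to every retained column; this is
asserted in the tests at 1e-8 relative.

Smoothing follows regression (the order is configurable): per-volume Gaussian
with σ = FWHM/(2√(2 ln 2)) per axis in voxel units, reflective boundaries
(which conserve the volume mean and avoid edge attenuation on small grids),
FWHM default 6 mm.

## Targets

Anatomical targets are unweighted ROI means. Network targets come from
stage-1 dual regression: at each time point the in-brain voxel intensities
are regressed on all K network templates jointly plus an intercept, and the
coefficient of template k over time is network k's series. Joint regression
(rather than one template at a time) mitigates template overlap; templates
are z-scored within the brain mask so coefficients are comparable across
networks, which also makes the series invariant to template rescaling. A
global per-time-point additive shift is absorbed by the intercept. Collinear
template pairs are rejected with an error naming the most correlated pair.

## Wavestrap significance testing

The null hypothesis is "the decoder's accuracy is what temporally misaligned
labels with the same spectral content would achieve". A surrogate label
series is built by a multilevel discrete wavelet decomposition of y_train
(4th-order Daubechies, filter length 8, symmetric extension), independently
permuting the detail coefficients within each level, leaving the
approximation coefficients untouched, inverting the transform, and truncating
to the original length. The level count is ⌊log₂(T/(L−1))⌋ with L the filter
length, which keeps the coarsest sub-band longer than the filter — four
levels at T = 182. Each surrogate trains a fresh SVR and predicts the *true*
held-out labels; the resulting correlations form the null. The p-value uses
the add-one convention p = (1 + #{r_surr ≥ r_true})/(1 + N), so p is never
zero and ties count against the null; the plain proportion is available by
flag. Per-level permutations are independent rather than shared, a choice the
surrogate literature leaves open. p-values are reproducible bit-for-bit for a
fixed (seed, N), and BH-FDR correction is applied over the full analysis
family of targets × feature modes.

The calibration study (tests and acceptance script) uses T = 64, F = 10
independent noise features, 200 replicates × 99 surrogates with the SVM-light
default C — sizes chosen so the uniformity check has binomial power without
dominating the suite's runtime — and requires the 5% rejection rate to land
in the 95% binomial interval. Power is checked separately on genuinely
coupled features, where p must pin to its minimum attainable value.

## Group maps and recursive subdivision

Per-subject voxel weight maps for one target are combined with a voxelwise
one-sample t-test against zero (no per-subject normalization — an open
convention; a unit-norm option would be a one-line change at the call site).
Voxels with zero between-subject variance, including voxels outside every
subject's support, are excluded from both the test and the FDR family. The
FDR-thresholded mask (q = 0.05) is clustered at 26-connectivity ("within one
grid cell in any direction" includes diagonals; 6-connectivity is a flag),
discarding clusters under 5 voxels, ordered by descending size with
lexicographic tie-breaks.

Each cluster larger than 40 voxels is split by the plane normal to the vector
v between its two farthest voxel centers (exact O(n²) scan, ties broken by
the lexicographically smallest coordinate pair) through their midpoint;
voxels with v·p ≤ b go to side 1. If a cut leaves one side empty (all
projections equal — measure-zero on real data, routine on lattices), a stable
median split of the projections is used instead, so every split strictly
shrinks the largest piece and termination is guaranteed. The recursion is
fully deterministic; subdivisions are reported with centroid (mm), volume
(mm³ = count × voxel volume; 40 voxels at 4 mm isotropic = 2,560 mm³) and
split history. One feature per subdivision = the unweighted mean series of
its member voxels.

## The synthetic generator

`synthetic.simulate_dataset` emulates the statistical structure the decoder
relies on, not the physics of BOLD. The brain is a flattened ellipsoid
(semi-axes 0.8 of the half-extent, inferior cap removed) on a 24³ grid of
4 mm voxels. Each of K latent networks is an AR(1) series (coefficient 0.5,
exactly standardized) — autocorrelated so the wavestrap has a non-flat
spectrum to preserve — mixed into (a) an interior ROI placed deeper than
21 mm, i.e. below any tested mask thickness, and (b) a patch of topmost
superior-shell voxels, which survive the inferior exclusion at every
thickness. Per-voxel mixing weights are drawn once (uniform 0.5–1.5 times the
effect amplitude) and shared across subjects and runs, like maps in a common
space; latent draws are independent per subject and run, matching the
split-half design. "Null" networks have an interior ROI but no surface patch:
their signal is invisible from the surface, giving a built-in chance-level
control. On top of the signal: per-voxel random polynomial drift from the
same degree-0..4 family the preprocessing removes, WM/CSF-like series carried
by dedicated interior blobs (whose mask means recover them) and mixed into
brain voxels with random weights, six motion-like random walks written to the
motion table and mixed in likewise, and white voxel noise. Defaults: T = 180
at TR 2 s (a 6-minute run), two runs, noise sd 1, effect amplitude 1, drift
amplitude 1, nuisance amplitude 0.5.

Because drift and nuisance terms lie exactly in the span of the nuisance
design, setting the noise to zero makes the pipeline exactly invertible: the
cleaned surface features and the cleaned target are the same linear filtering
of the same latents, and cross-validated r reaches ≥ 0.99 for every coupled
target — the recovery spine of the test suite. What passing these tests does
*not* show: robustness to hemodynamic convolution, physiological noise
spectra, realistic motion artifacts, inter-subject anatomical variability, or
registration error, none of which the generator models.

## Problem sizes and numerical choices

The shipped experiments use 3 test subjects (2 runs each), a 10-subject
group for subdivisions, 4 networks, and 24³ × 180 runs — sizes at which the
full pipeline, the 200-replicate calibration and the depth sweep together
complete in a few minutes on one CPU while keeping every Monte-Carlo
assertion comfortably powered. The accuracy-vs-depth slope is reported as
computed (no reference value exists for synthetic data, where information
density over depth is uniform by construction and the slope is expected to
hover near zero). Distance-transform, clustering, t-test p-values, DWT and
BH-FDR go through scipy/statsmodels/PyWavelets; the mask morphology, the
wavestrap permutation scheme, the farthest-pair plane subdivision and the
SVM-light default-C rule are implemented here and each is tested against an
independent brute-force oracle.

## Known limitations

- Oblique or non-axis-aligned volumes are rejected, not resampled; inputs
  must already be in a shared space.
- The Chebyshev depth metric requires isotropic voxels.
- Wavestrap nulls at C = 100 on large voxel feature sets are expensive
  (surrogate labels are unrealizable targets, the SMO worst case); the
  iteration cap bounds each fit, but large-scale significance runs are best
  done on subdivision features or with the default-C setting.
- The group t-test assumes subject weight maps are exchangeable and
  approximately normal per voxel; with very few subjects the FDR mask is
  conservative.
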