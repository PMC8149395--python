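# Methods

This note documents the models, numerical choices and validation logic of
`hippofc`, in the order the pipeline runs them.

## Synthetic cohort

The phantom generator is first-class, tested code; its defaults describe
the acquisition the pipeline targets: 16 subjects, 180 timepoints at
TR = 2 s, seven cortical networks.  Geometry and signal model:

* **Voxel grid.**  Two hemisphere grids (default 12 × 4 × 4 voxels each)
  sit side by side along axis 1 with a one-voxel background gap.  Axis 0
  is the hippocampal longitudinal (anterior→posterior) axis.  Voxel
  coordinates are 0-based integer indices; a series row is addressed by
  the voxel's flat C-order index.
* **True parcels** are contiguous longitudinal slabs.  A configurable
  fraction (default 0.35, i.e. roughly one third mirrored and the rest
  unilateral) occupies the same slab in both hemispheres under one label;
  the remaining extent is tiled by unilateral slabs split as evenly as
  possible between hemispheres.  Parcels partition the mask by
  construction and every parcel gets ≥ 8 voxels, otherwise the spec is
  rejected as unsizeable.  A single unilateral parcel is impossible (it
  cannot tile both hemispheres) and is rejected with a clear error.
* **Anatomical labels** are lamellar shells along the dorsal–ventral axis
  spanning the full longitudinal extent, bilaterally symmetric — the toy
  analogue of subfields such as CA1/CA3/CA4-DG/subiculum (default 4
  labels).
* **Latents.**  Each parcel carries a band-limited (0.01–0.1 Hz) latent
  per subject, synthesised directly in the frequency domain (random
  complex Gaussian coefficients on in-band rFFT bins, zeros elsewhere) and
  standardised exactly; out-of-band power is therefore ~0 and the
  0.01–0.1 Hz band is the generator's native habitat.  A warning is
  issued when the scan duration cannot resolve the lower band edge.
* **Signal model.**  Voxel in parcel j: `u_j(t) + e(t)/snr` with i.i.d.
  standard-normal noise.  Vertex in network m: the unit-variance
  normalisation of `Σ_j C[j,m]·u_j(t)` plus noise of the same scale,
  where C is the parcel→network connectivity matrix (default: one-hot,
  parcel j → network j mod n).  `snr` is signal sd / noise sd; the
  effective SNR of sub-millimetre 7 T hippocampal voxels is not a known
  quantity, so snr is a free parameter (default 2, the value the recovery
  experiments use and sweep).
* **Covariates.**  The tSNR proxy is a baseline-to-fluctuation ratio of
  the whole-hippocampus mean series (baseline 100 a.u.) plus unit-normal
  jitter; gender alternates 0/1.  Both exist to exercise the group-GLM
  covariate path.
* **Noise is white** by design: no physiological noise, autocorrelation,
  motion, or susceptibility dropout.  This keeps the sign-flip permutation
  null exact and the recovery targets interpretable — and it means passing
  tests demonstrate correctness of the machinery, not robustness to the
  artefact structure of real scanner data.

Everything is a pure function of the spec and its `rng_seed`; latent and
noise streams are derived independently so the geometry can be reused.

## Preprocessing

* **Band-pass filter**: order-4 Butterworth (per band edge) applied
  forward–backward (`sosfiltfilt`), i.e. zero-phase with squared
  magnitude response.  The response at the passband interior (0.05 Hz for
  the default 0.01–0.1 Hz band) deviates from unity by far less than 5 %,
  and one octave outside the band the attenuation exceeds 20 dB by orders
  of magnitude.  No filter family is canonical for this step; Butterworth
  was chosen for its flat passband.  Series shorter than three filter
  lengths are rejected rather than padded.
* **Surface smoothing** is iterated symmetric diffusion
  `x ← x − λ(D − A)x` with λ = 1/(max degree + 1).  The combinatorial
  Laplacian has zero row and column sums, so the field mean is preserved
  exactly, and every update is a convex combination, so extremes never
  grow.  The iteration count for a requested FWHM is calibrated once per
  mesh by diffusing a unit impulse at the most central vertex and
  measuring the literal full width at half maximum (twice the
  interpolated half-maximum radius of the distance-sorted profile);
  moment-based width estimates were rejected because the discrete kernel
  has a heavier-than-Gaussian centre.  A target FWHM below the mean edge
  length cannot be represented by neighbour averaging and returns the
  input unchanged with a warning.
* **Depth-restricted sampling** averages each vertex's samples from the
  mid-cortex-to-white-matter depth range; with one synthetic value per
  vertex it is an identity pass-through.  Vertices without samples are
  flagged missing and excluded downstream, never imputed.

## Functional segmentation

* **Group spatial ICA.**  Subjects are concatenated along time; each
  voxel's series is demeaned; SVD reduces to k dimensions; the left
  singular vectors, rescaled to unit variance per dimension, are rotated
  by fixed-point negentropy ICA (FastICA, logcosh).  The unit-variance
  rescaling matters: on norm-1 singular vectors the logcosh contrast
  operates in its near-linear regime and the rotation stalls at mixtures.
  Time courses are recovered by least squares against the source maps.
  Maps are standardised and sign-fixed so skewness is nonnegative.  If
  the numerical rank is below k, k is reduced with a warning.
* **Probability maps.**  Each component map becomes the posterior
  probability of the "active" class under a two-component Gaussian
  mixture with shared variance fitted by EM.  The shared variance makes
  the posterior a logistic function of the map value, hence monotone —
  a property the clustering relies on.  Degenerate fits (collapsed means,
  empty component) fall back to a logistic transform of the standardised
  value and are flagged in the QC report.
* **QC screen.**  A component fails if more than 25 % of its time-course
  spectral power lies above 0.1 Hz, or, when an exclusion mask (e.g. a
  CSF proxy) and component FC maps are supplied, if the map–mask
  correlation exceeds 0.5.  Failed components are dropped *before*
  feature building, and the decision is recorded in the QC report.
* **Clustering.**  Euclidean k-means over per-voxel probability profiles,
  ≥ 10 restarts, best within-cluster sum of squares kept, deterministic
  given the seed.  The validity index is the mean point-to-own-centroid
  distance divided by the mean pairwise centroid distance.  The cluster
  count is the knee of the CVI curve: after min-max normalisation of both
  axes, the k maximising the perpendicular distance to the chord joining
  the curve's endpoints; all ties (including a perfectly linear curve)
  resolve to the smallest k, with a warning when no interior knee exists.
* **Ordering.**  Final labels are sorted by longitudinal centroid
  (anterior first); ties break by medial–lateral centroid, then label.

The recovery experiments feed `parcellate()` the raw simulated series
rather than band-passed ones: planted noise is white, so the spectral QC
can identify and drop pure-noise components, mirroring its role on real
data where high-frequency structure marks artefactual components.  Group
ICA uses 8 components for the 6-parcel phantom (the anatomical-label count
of the phantom, 4 lamellae × 2 hemispheres), leaving headroom that the QC
screen is expected to absorb.

## iFC mapping and permutation correction

* Seed time courses are unweighted voxel means.  Pearson correlations of
  flat (zero-variance) vertices are set to 0 and flagged.  |r| = 1 is
  clamped to 1 − 1e-7 before the Fisher transform and flagged.
* The group GLM is a vectorised per-vertex OLS of z on an intercept plus
  mean-centred covariates; the tested contrast is the intercept (group
  mean at average covariate values), two-sided, with
  df = subjects − covariates − 1.  A rank-deficient design is rejected.
* **Permutation correction.**  Cluster-forming threshold: the two-sided
  `vertex_alpha` t-quantile.  Subject maps are residualised against the
  centred covariates (the group mean — the tested effect — stays in), and
  each permutation flips whole subjects' signs, which is exact under the
  symmetric null the white-noise generator provides.  Suprathreshold
  |t| vertices are clustered by edge connectivity on the triangle mesh;
  the cluster statistic is vertex count (extent).  The identity
  permutation is always included.
* **Mid-p correction for discreteness.**  Cluster extent is an integer,
  so its max-statistic null is discrete and a plain exceedance count is
  systematically conservative: on a 500-vertex mesh at the default
  thresholds the achievable family-wise levels jump from ≈ 0.078
  (extent ≥ 4) straight to ≈ 0.016 (extent ≥ 5), bracketing — never
  attaining — the nominal 0.05.  The corrected cluster p is therefore the
  mid-p of the permutation null (full weight on strictly larger null
  maxima, half weight on ties), the standard calibration-preserving
  treatment of discrete permutation statistics; the calibration test
  verifies the resulting family-wise error rate empirically.  Corrected
  p-values convert back to signed z-scores (sign of the cluster's mean t)
  on significant vertices.
* Whether extent or mass is the better cluster statistic, and the
  sidedness of the forming threshold, are genuinely open conventions;
  extent and two-sided |t| are used here and recorded in the run
  manifest so alternates can be swapped.

## Network metrics

Coverage c_i is the percent of network i's *vertices* inside a
significance mask (vertex count, not surface area, is the denominator —
an explicit choice; area weighting would need per-vertex areas the toy
mesh makes uniform anyway).  ν consumes the normalised vector, so storing
c in percent is immaterial (tested to 1e-12).  An all-zero coverage
vector raises: ν is undefined there, and silently returning 0 would
misreport a seed with no significant connectivity as "perfectly uniform".
Tertile grouping sorts by descending ν, splits remainders toward the
higher groups, and breaks ties by seed id.  Dice of two empty masks is
reported as missing, not 0 or 1.

## Pipeline

Stages (`simulate → parcellate → connect → score`) communicate only
through declared file artifacts in the run directory, so each stage is
independently re-runnable.  All stage seeds derive from the single
top-level `rng_seed`; manifests carry the config, its hash and the
derived seeds, and contain no timestamps so identical configs produce
bit-identical manifests.  Defaults follow the target acquisition (band
0.01–0.1 Hz, FWHM 3 mm, ICA k = 24, cluster scan 2..24, 4000
permutations, thresholds 0.05); synthetic runs typically reduce `n_perm`
to a few hundred, and whatever value is used is recorded in the manifest.

## Problem sizes used in validation

The test suite uses a 6-parcel phantom (384 hippocampal voxels, 8
subjects, 180 timepoints), 500–700-vertex planar meshes, 300–1000
permutations, and 20-replicate recovery experiments; the family-wise
error calibration runs 200 independent null datasets.  These sizes give
stable Monte-Carlo estimates for the quantities being checked while
keeping the full suite in the low minutes.

## Known limitations

* The generator's white noise and block-structured connectivity make
  recovery easier than on real data; passing tests validate the
  machinery, not robustness to physiological artefacts.
* The permutation test assumes subject exchangeability under sign
  flipping; heavy-tailed or asymmetric subject effects would weaken its
  exactness.
* The Gaussian-mixture probability maps assume a unimodal null and a
  single active mode per component; multimodal component maps would
  violate this.
* Real-data mode consumes NIfTI/GIFTI inputs through the same interfaces
  but registration, denoising and anatomical segmentation are out of
  scope and must be done upstream.
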