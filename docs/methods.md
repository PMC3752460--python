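# Methods

This note records the statistical model behind `rsndr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Data model and geometry

All stages operate on a fixed voxel grid shared by every volume, mask and
covariate map. Nothing resamples or registers: grid mismatches are errors
(`volio.GridMismatchError`). Volumes are NIfTI-1 with RAS+ affines; masks
are stored as 8-bit 0/1 integers; design tables are tab-separated text with
a header (`subject_id`, `group` ∈ {patient, control}, `bold_path`,
optional `gm_path`).

## Synthetic cohorts

Each subject's signal is a linear mixture plus noise:

    y(v, t) = Σ_k m_k(v) · c_k(t) + ε(v, t),   ε ~ N(0, noise_std²) i.i.d.

* **Spatial networks** `m_k`: isotropic Gaussian blobs, max 1, with
  rejection-sampled centres at least `min_center_separation` voxels apart
  inside the brain ellipsoid. The configuration supports up to 70 networks
  (the model order typical of high-order group ICA studies) on
  sufficiently large grids.
* **Time courses** `c_k`: white noise hard-masked in the frequency domain
  below `lowpass_hz` (default 0.08 Hz, the conventional upper edge of
  resting-state BOLD fluctuations), then rescaled to an exact target
  standard deviation. The hard mask makes the band-limiting property exact
  and testable; the exact rescaling puts all between-subject amplitude
  variability under the experimenter's control.
* **Defaults** mirror the emulated acquisition: 19 patients vs 19
  controls, 285 time points at TR 1.8 s, nominally 4 mm voxels. The
  default test grid is 24×24×16 — large enough for genuine 3D cluster
  geometry, small enough that replicated studies run on a desk.
* **Planted effects** (patients only): `amplitude_ratio` scales a
  network's time-course std; `spatial_shift` adds an extra blob to the
  patient map; `atrophy = (center, radius, gm_reduction,
  bold_attenuation)` multiplies gray-matter density by `1 − gm_reduction`
  and all network weights by `1 − bold_attenuation` inside a sphere. GM
  reduction and BOLD attenuation are deliberately separate knobs so
  confound-adjustment experiments can toggle them independently, although
  in real anatomy they co-occur.
* **Gray-matter maps**: baseline 0.7 inside the brain ellipsoid, minus
  atrophy spheres, plus per-subject N(0, 0.02) jitter, clipped to [0, 1].
  The jitter gives the voxel-wise covariate genuine within-group variance.
* **Determinism**: a cohort is a pure function of (config, seed);
  per-subject seeds are spawned from the cohort seed via
  `numpy.random.SeedSequence`. Planted time courses are stored on the
  cohort so recovery tests have exact ground truth.

What the generator does **not** emulate: hemodynamic response convolution,
physiological (cardiac/respiratory) noise, head motion, scanner drift,
spatial noise autocorrelation, and registration error. Passing tests
therefore demonstrate the statistical machinery under the model's own
assumptions — exchangeable subjects, i.i.d. Gaussian noise — not
robustness to real-scanner artefacts.

## Group ICA

Per-subject variance normalization (each voxel time series demeaned and
scaled to unit variance; zero-variance voxels zeroed and flagged), temporal
concatenation, then spatial ICA at a user-set model order. The
decomposition is scikit-learn's `FastICA` — fixed-point iteration with the
tanh (logcosh) contrast and symmetric decorrelation — applied to the
voxels × time matrix so sources are spatial maps and the mixing matrix
holds group time courses; its internal SVD whitening performs the
dimensionality reduction. Automatic model-order estimation is out of
scope: the order is a user choice, as it was in the study design this
emulates. Maps are z-scored over the mask (demean, unit variance) and
sign-flipped to positive spatial skewness; with a fixed seed the output is
bit-reproducible. Non-convergence raises by default (`strict=True`) and
downgrades to a warning otherwise.

A consequence of *total*-variance normalization worth knowing: a planted
map `m_k` appears in the normalized data as
`amp_k·m_k(v) / sqrt(Σ_j amp_j² m_j(v)² + noise²)`. Recovery tests
therefore compare recovered components against this analytic effective map
(`synthetic_data.effective_network_maps`), not the raw blob. In the
noise-free limit the effective map degenerates to the blob's support
indicator, which is why ICA correctness tests at zero noise use
compact-support sources.

### Mixture-model thresholding

Component z-maps are thresholded by a three-class mixture: Gaussian null
plus an offset gamma for the positive tail and a mirrored offset gamma for
the negative tail, fitted by EM; a voxel survives when its posterior null
probability (local FDR) is below 0.5. Numerical choices: moments
initialization (null centre/scale from median and IQR; tail classes from
the mass beyond 2σ), gamma offsets frozen at the initial null centre so
that every M-step is an exact weighted MLE and the log-likelihood is
provably non-decreasing, 500 iterations max, relative tolerance 1e-8. A
tail weight collapsing to zero means "no activation of that sign" and is
reported, not raised. The z-scoring here is plain demean/unit-variance of
the map; reference ICA tools normalize by a residual-noise estimate
instead, so absolute thresholds are not directly comparable between the
two conventions.

## Dual regression

Stage A regresses each time point's voxel pattern (demeaned over the mask)
on the demeaned template maps — all maps in one multiple regression, so
overlapping networks are jointly unmixed. Stage B regresses each voxel's
demeaned time series on the stage-A time courses (columns demeaned;
scaled to unit *standard deviation* when `des_norm=1`). Demeaning plays
the role of the intercept throughout; for balanced inputs an explicit
constant column would change nothing. Rank deficiency of the template over
the mask raises an error naming the near-collinear pairs (|r| > 0.999);
least squares is solved by LAPACK SVD (`lstsq`) with a relative rank
tolerance of 1e-10; a zero-variance time course yields zero betas and a
flag rather than a division.

Known second-order effect: stage-A time courses are estimates, so stage-B
betas carry an errors-in-variables attenuation `var(c)/(var(c)+v_e)`
where `v_e` is the projection noise. With `des_norm=0` a pure amplitude
difference between groups is *almost* invisible in the betas, but the
attenuation differs slightly between groups; with overlapping networks and
small within-group variance this residual bias can reach |t| ≈ 3–4 in a
single cohort. The test suite therefore checks the des_norm contrast on a
replicate median, and single-subject amplitude contracts on noise-free
constructions where the identity is exact.

## Inference

* **t statistics**: pooled-variance two-sample t per voxel; with a
  voxel-wise covariate, the t of the group coefficient in
  `beta ~ 1 + group + GM(v)` (per-voxel normal equations, batched
  pseudoinverse; zero residual variance ⇒ t = 0, never significant).
* **TFCE**: `TFCE(v) = Σ_h extent_h(v)^E · h^H · dh` with H = 2, E = 0.5,
  100 midpoint-rule steps (`dh = max/100`), 26-connectivity — the standard
  parameterization of the technique. Only positive values are enhanced;
  the opposite contrast is run on the negated map. The kernel processes
  thresholds in descending order with an incremental union-find, giving
  near-linear cost per map; it is JIT-compiled with numba and verified
  against an explicit per-threshold labelling oracle (exact at matched
  steps; ~1% quadrature difference against a 10×-finer integration, which
  is the accuracy of the 100-step rule itself).
* **y-concatenation**: blocks (one per component) share the subject axis
  and a single permutation stream; the null distribution is the maximum
  TFCE value over *all* blocks per permutation. Blocks are joined
  statistically rather than stacked geometrically, so clusters can never
  bridge two components — a deliberate resolution of the ambiguity in a
  literal image-space concatenation.
* **Permutation scheme**: group labels permuted by a seeded generator;
  when the number of distinct label arrangements is ≤ `n_perm` (and no
  covariate is involved) the null is enumerated exhaustively instead.
  Corrected p uses the add-one estimator, `p ≥ 1/(n_perm+1)`, and
  significance is strict (`p < α`; a tie at α is excluded). Default
  `n_perm = 5000`, α = 0.05; below 1000 permutations a coarseness warning
  is issued, below 100 it is an error.
* **Covariate handling**: Freedman–Lane — fit the reduced (covariate-only)
  model per voxel, permute its residuals, add back the reduced fit, re-test
  the group term in the full model. This is the accepted scheme for
  permutation with nuisance regressors. The GM covariate must already live
  on the analysis grid; `smooth_volume` provides Gaussian smoothing with
  sigma in mm (FWHM = 2.355·σ, default usage σ = 3 mm) to match how
  VBM-style gray-matter maps are conventionally prepared.
* **Directions**: contrasts are one-sided and each direction is corrected
  separately, matching directional reporting of group increases.

## Summaries

`difference_map_stats` reports, per component, the significant-voxel count,
the (0-based voxel-index) location of the peak t, and min/max/mean/std of t
within the significant mask; the std is the population form (divide by n)
so a single-voxel region reports 0 rather than NaN. `atrophy_adjacency`
computes the fraction of significant voxels inside an atrophy mask and
within each distance d of it, using a Euclidean distance transform in voxel
units (deterministic; mm distances are available through the affine if
needed). `near_fraction` is monotone in d by construction.

## Validation studies and problem sizes

`rsndr.studies` packages the replicated experiments the test suite and the
reproduction script both run; sizes were chosen as the smallest that keep
the relevant sampling errors meaningful on a single CPU:

* **FWER calibration**: 200 global-null cohorts (24×24×16 grid, ~550-voxel
  mask, n = 8 vs 8, 6 networks, T = 285), dual regression against the truth
  atlas, joint 6-block test at 250 permutations; the single-map error rate
  is read off the same permutation stream (block-wise null maxima), making
  the joint-vs-single comparison exactly paired. 200 replicates give a
  binomial standard error of ~0.015 at a true rate of 0.05; the
  reproduction script runs 600 replicates of the same harness to tighten
  that standard error to ~0.009.
* **Power**: amplitude ratio 2 on one network, n = 10 vs 10, des_norm on,
  detection = jointly-corrected significant voxels overlapping the truth
  blob; 50 replicates.
* **Confound adjustment**: patients carry an atrophy sphere
  (gm_reduction = bold_attenuation = 0.35, radius 2.5 voxels) at one
  network's centre and *no* amplitude effect, so every group difference is
  GM-mediated; the joint test runs with and without the voxel-wise GM
  covariate on the same cohorts, 20 replicates. Because the covariate is
  nearly collinear with the group label at affected voxels, the adjusted
  group term loses identifiability exactly where the confound acts — which
  is the desired behaviour: those voxels stop being attributed to group.

## Known limitations

* Total-variance (not residual-noise) normalization in group ICA shifts
  mixture-threshold scales relative to reference tools.
* The permutation engine covers two-group designs only; paired designs,
  continuous covariates of interest, and spatial-autocorrelation-aware
  nulls are out of scope.
* Exhaustive enumeration is not combined with Freedman–Lane resampling;
  covariate runs are always Monte Carlo.
* The generator's effect sizes are free parameters; nothing calibrates
  them to any particular patient population.
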