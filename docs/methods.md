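# Methods

This note documents the models, algorithms and numerical choices behind
`olfica`, and what the synthetic validation study does and does not show.

## Signal model and simulator

The simulator emulates a two-run olfactory identification task: per run,
8 odorants × `reps_per_run` presentations, each a 16-s stimulation+choice
event, with a 16-s baseline block after every set of eight; TR = 2 s. Each
stimulus event is a hit with probability logistic in the subject's SDOIT
score (intercept 0.4, slope 0.35 per point around a score of 4), so
identification ability and in-scanner accuracy correlate, and hit/miss
imbalance — including subjects with no misses in a run — is exercised.
The default schedule (4 repetitions) needs 288 frames/run; the validation
cohort uses 2 repetitions in 160 frames to keep desk-scale runtimes.

BOLD is linear in `C` planted networks: each network is a sum of 1–3
Gaussian blobs (unit peak, pairwise spatial |r| < 0.2 by construction,
placed away from the noise-region box), and its timecourse is

    tc_c = a_hit,c · x_hit + a_miss,c · x_miss + intrinsic_c

where `x_hit`, `x_miss` are HRF-convolved condition boxcars and
`intrinsic_c` is a smoothed Gaussian process (SD 1.0, ~3-frame smoothing).
The intrinsic term is not decoration: without it every timecourse lies in
the 2-dimensional span of the condition regressors, the data matrix has rank
2, spatial ICA cannot separate more than two networks, and the gPPI design
is exactly collinear (seed = combination of hit and miss columns). The
z-scored planted maps (zero mean, unit SD over the analysis mask) are used
as the mixing loadings so that condition betas are expressed directly in
planted-amplitude units.

One designated network's hit amplitude is a linear function of the centered
covariates with coefficients mirroring a plausible moderation structure
(ApoE main effect −0.25; three-way ApoE×SDOIT×familiarity 0.078; small
lower-order terms). One network is the gPPI seed: during hit events its
centered timecourse couples into a compact ~30-voxel target ball with gain
0.5 (a connected cluster, so spatial smoothing does not annihilate it).

Noise is AR(1)-filtered thermal noise (φ = 0.3, SD 0.5), a per-voxel linear
drift (slope SD 0.5), and — at frames where the motion simulator planted a
>1 mm jump — a global intensity offset (SD 3.0), so FD/DVARS spike detection
has a physical correlate in the images. A corner box of the grid is a
"CSF-like" noise region (shared 0.08-Hz physiological factor plus thermal
noise) feeding aCompCor; it is excluded from the analysis mask. Covariates
follow the target population: ApoE carrier fraction 16/36, SDOIT integer
0–8 (mean 4.4, SD 2.0), familiarity 1–10 (mean 4.7, SD 1.9), age 76.6 ± 4.2,
female fraction 20/36.

What the simulator does **not** model: hemodynamic nonlinearity and
saturation, susceptibility artifacts, spatial autocorrelation of thermal
noise, anatomical variability, registration error, and any non-neural
covariate structure. Passing tests therefore demonstrate the correctness of
the estimation machinery under the assumed linear model, not robustness to
the full artifact repertoire of real fMRI.

## HRF and task regressors

The canonical HRF is a double-gamma (response gamma shape 6, scale 1 —
peaking at 5 s; undershoot shape 16, ratio 1/6), truncated at 10 s and
peak-normalized. The short truncation is deliberate: with long (16-s)
stimulation events a compact kernel correlates best with task-locked
component timecourses, and normalization pushes scale into the betas.
Regressors are boxcars sampled at the TR and convolved at TR resolution —
at 16-s events and TR 2 s, microtime upsampling changes regressors
negligibly (an upsampling factor remains configurable). The kernel is
exactly 0 at t = 0 (gamma density at the origin), so a regressor's support
begins one frame after the event-onset frame.

## Group ICA

Reduction is the standard two-stage scheme: per subject, voxelwise temporal
mean removal and SVD projection to `l1` temporal dimensions (default
round(1.5·C)); concatenation across subjects on the reduced dimension; group
SVD to `C` whitened dimensions. All projection matrices are retained.

Model order uses the Wax–Kailath MDL form on the eigenspectrum,
`MDL(k) = −N(p−k)·log(g_k/a_k) + ½k(2p−k+1)·log N`, with the effective
sample size `N` configurable (defaulting to the voxel count); no
i.i.d.-subsampling correction is applied. On white noise the criterion
returns the floor of 1.

Infomax maximizes entropy through a logistic nonlinearity by full-batch
natural-gradient ascent (learning rate 0.01, annealed ×0.97 whenever the
update direction swings by more than 60°). Iteration stops when the applied
weight-change norm falls below 1e-6; the step budget is 4096 because
convergence to that tolerance takes ~1500–2100 steps at these problem sizes,
and stopping earlier leaves ICASSO clusters visibly unstable. Divergence
triggers up to 3 restarts at halved rates. Runs are deterministic per seed.

ICASSO re-runs infomax from `n_runs` (default 10) random initializations —
random initialization only, no bootstrap resampling — pools the estimates,
clusters them by average linkage on 1 − |r|, and keeps per-cluster
centrotypes with quality index I_q = mean within-cluster − mean
between-cluster similarity. Each centrotype source is sign-fixed (extreme
voxel positive) and scaled to unit voxel variance, so the z-scored aggregate
map and its timecourse remain a consistent factorization of the data —
physical amplitude lives in the timecourse. Without this normalization,
interaction betas in the gPPI stage would be off by the arbitrary source
scale.

GICA3 back-reconstruction uses the partitioned projection: subject
timecourses `TC_i = F_i G_i D^{1/2} A` and subject maps
`S_i = M · W D^{−1/2} G_iᵀ Y_i`. The defining property — the mean over
subjects of `S_i` equals the aggregate source matrix — is exact by
construction (machine precision in practice), and for exact-rank data
`TC_i S_i` reproduces the centered subject data.

## Sorting and retention

Correlations with the generic task regressor are computed per run (run
boundaries never enter one correlation) and aggregated as the mean of |r|
over subject-runs; retention is strict (> 0.2), so a component at exactly
.2 is excluded. Aggregation by mean-of-|r| (rather than mean of signed r)
matches the magnitude-based retention rule; signed aggregation is a config
switch. Condition betas use OLS with per-run intercepts and shared hit/miss
columns; a condition empty for a subject is dropped from that subject's
design and reported as missing (NaN), never as zero.

## TMFC (gPPI)

The seed and the psychological regressors are centered per run before the
interaction products are formed, which makes the interaction betas exactly
invariant to constant offsets of either parent and to any signal lying in
the nuisance column space. No hemodynamic deconvolution of the seed is
performed: interactions are formed directly on the observed timecourse
against HRF-convolved psychological regressors (deconvolution is ill-posed
at TR 2 s with 10-s kernels; a boxcar-psychological switch exists). Both
runs are fitted in one concatenated model with per-run intercepts and
per-run DCT bases; both condition interactions sit in a single design (gPPI
style). Estimation is plain OLS via one pseudo-inverse applied to all
voxels — no AR(1) prewhitening, matching ordinary PPI practice. All-zero
columns are dropped and logged; rank deficiency among task+interaction
columns raises an error naming the most collinear pair.

## Group statistics

One-sample t maps use the textbook per-voxel formula with df = n−1 and
two-tailed p. The moderation design has 10 columns (intercept, ApoE, sex
uncentered 0/1; SDOIT, familiarity, age centered; three two-way products and
the three-way product of centered terms). The highest-order coefficient is
invariant to the centering, which the tests verify to 1e-10. Cluster-extent
thresholding binarizes two-tailed voxel p, clusters positive and negative
statistics separately by connected components (connectivity 26 by default;
6/18 available), and discards clusters below the extent. No multiplicity
correction beyond voxel+extent is applied — the three-way interaction is
treated as exploratory. Marginal means are predicted over an SDOIT grid for
ApoE ∈ {0,1} × familiarity at mean ±1 SD, sex weighted 0.5 and age at its
mean, with extrapolation beyond the observed SDOIT range flagged.

## Numerical and validation choices

- **Validation problem sizes.** The ICA validation cohort is 10 subjects on
  a 15×15×12 grid, 160 frames × 2 runs — small enough to run in seconds,
  large enough that matched map recovery exceeds |r| = 0.95 and I_q > 0.97.
  The moderation Monte-Carlo uses 200 replicates at n = 34 with outcome
  noise SD 0.1 ("small" relative to the 0.8 base amplitude); the type-I
  study uses 20 null replicates of 12³-voxel outcomes.
- **Exactness tests.** The planted three-way coefficient is recovered to
  1e-6 end-to-end on a noiseless cohort when the spatial unmixing is exact
  (least squares against the planted maps): every stage downstream of the
  unmixing — back-reconstruction, sorting, condition betas, group
  regression — is deterministic linear algebra. Infomax itself separates
  correlated-but-not-independent blob maps only approximately (|r| ≈
  0.96–0.999), so ICA-path recovery is asserted at correlation level, not
  at 1e-6.
- **DVARS spikes.** A one-frame intensity offset produces DVARS excursions
  at the spike frame *and* the following frame (the return to baseline);
  the spike-flagging test asserts exactly that pair. "2 mm of DVARS" is not
  dimensionally meaningful for raw DVARS, so the threshold (2.0) applies to
  the median-standardized series by default; raw thresholding is a config
  switch.
- **Degenerate inputs.** Zero-variance maps, empty masks, saturated spike
  designs, rank-deficient group designs (e.g., carrier status aliasing sex
  in a small draw) and missing conditions all raise informative errors or
  flags rather than propagating NaNs; small covariate samples can
  legitimately produce an aliased 10-column design, which is reported with
  the offending column names.

## Known limitations

- The MDL criterion is applied without GIFT-style subsampling correction;
  on strongly autocorrelated real data it will overestimate the order unless
  the effective sample size is reduced via configuration.
- ICASSO uses random initialization only; bootstrap-based stability would
  additionally probe sampling variability.
- OLS without prewhitening understates autocorrelation-induced variance in
  single-subject GLMs; group-level inference (the level at which conclusions
  are drawn) is unaffected under exchangeability across subjects.
- Anatomical labeling of clusters, registration/normalization, and realistic
  artifact models are out of scope.
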