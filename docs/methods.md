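# Methods

`capdyn` implements a seed-based co-activation pattern (CAP) analysis of
resting-state fMRI, together with a synthetic cohort generator that makes
every stage testable against known ground truth. This note describes the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic validation does and does not establish about real data.

## The analysis model

### Frame selection

A CAP analysis treats individual fMRI volumes ("frames") as samples of
transient whole-brain states. The per-volume seed signal (mean over the seed
voxels of the cleaned data) is z-scored over time, and frames with seed
z > 0.84 are selected as high-amplitude events — under a Gaussian seed signal
this keeps the top ~20 % of volumes (1 − Φ(0.84) ≈ 0.2005). All threshold
comparisons are strict (`>`), so a frame exactly at the threshold is
excluded. Motion scrubbing removes every volume with framewise displacement
(FD) > 0.5 mm together with its −1/+1 neighbours, using the conventional
six-parameter FD with a 50 mm head radius; the first volume has no
predecessor and gets FD = 0. A subject is excluded outright when more than
40 % of volumes exceed the FD threshold.

### Temporal cleaning

Cleaning is per run and strictly temporal (spatial preprocessing is assumed
done): OLS nuisance regression against a design of polynomial trends
(constant, linear, quadratic), the six rigid-body motion parameters, optional
tissue-average signals and the global signal (on by default, switchable —
global signal regression is a known reproducibility axis for CAP results),
followed by a 0.01 Hz high-pass. The high-pass is implemented as regression
on discrete-cosine drift basis functions below the cutoff rather than a
recursive filter, avoiding edge transients on ~300-volume runs; its contract
is spectral (≥ 90 % attenuation well below cutoff, ≤ 10 % distortion well
above), not bit-exactness against any particular filter.

### CAP construction

Retained frames from the reference group (controls) are pooled, reduced by
PCA to the smallest basis reaching 90 % explained variance (the retained
fraction is a config key; the cited CAP literature does not fix a number),
and clustered. The number of clusters K is selected by consensus clustering:
100 resamples of 80 % of frames, one k-means run each, consensus(i,j) =
co-assignment count / co-selection count, and PAC(K) = proportion of pairs
with consensus strictly inside (0.1, 0.9). The K minimizing PAC wins, ties
going to the smaller K. The final clustering is k-means with 50 restarts;
clusters are renumbered by descending size so "CAP 1" is the most frequent
reference state. CAP maps are voxel-wise means of member frames after
inverting the PCA projection, then spatially z-scored (mean 0, SD 1 across
voxels).

### Cross-group frame assignment

Each patient frame is correlated (Pearson, over non-seed voxels) with every
CAP map; it takes the label of the best-correlating CAP if that correlation
strictly exceeds the CAP's acceptance threshold — the 5th percentile of the
reference members' own correlations with their map — and is otherwise left
unassigned. By construction ~5 % of reference frames fall below their own
CAP's threshold, so exact self-consistency under re-matching is capped just
below 95 %; what the method must (and does) deliver is that frames are
almost never relabelled to a *different* CAP — the disagreement is the
designed rejection, not confusion between states. For target-group frames
the rejection rate roughly doubles (to ~10 % on the default synthetic
cohort): reference members are in-sample for their own maps, so the
acceptance thresholds are slightly optimistic for out-of-sample frames.
This is a property of the published rule itself, and it is why the
validation suite scores assignment accuracy as confusion-matrix accuracy
over assigned frames and reports the unassigned rate separately. The 5th-percentile distribution uses only the frames
belonging to that CAP (not all reference frames); the alternative reading is
noted as a sensitivity axis.

### Temporal metrics

For each subject and CAP, on the per-volume label series (codes: CAP 1..K,
unassigned, not-retained):

- **average duration** — mean length of maximal runs of consecutive volumes
  with that CAP label, times the TR (seconds). Runs are defined on original
  volume indices: a scrubbed or sub-threshold volume breaks a run (config
  `contiguity="retained"` provides the gap-bridging alternative). A CAP never
  visited yields a missing value, which propagates (it is not imputed as 0).
- **relative entries** — number of runs divided by the subject's retained
  frame count; a run starting at the first retained volume counts.
- **relative occurrence** — retained frames with that label divided by
  retained frames. Unassigned frames stay in the denominator, so occurrences
  sum to 1 only when every retained frame is assigned.

### Group inference

Each metric is modelled jointly over subjects and states:
`value ~ group × state + age + sex + psychotropic medication + mood score +
retained-frame count`, with a per-subject random intercept estimated by
REML. Post-hoc per-state group contrasts (control − patient, so a positive
estimate means the metric is lower in patients) are taken on the fixed
effects. Contrast standard errors use a cluster-robust (by subject) sandwich
covariance built from the fitted variance structure, with a t reference at
(subjects − 1) degrees of freedom. This robustification is deliberate: the
joint model pools residual variance and covariate slopes across states, and
when states differ in variance (low-occupancy states vary less) the
model-based contrast SEs are miscalibrated per state — in null simulations
the model-based version rejected at ~0.02–0.03 instead of 0.05, while the
cluster-robust version is calibrated (~0.057 measured overall). When the
REML fit fails the model falls back to OLS (a zero-variance random
intercept) with the same robust contrasts, and flags the rows.

All post-hoc contrasts from the three metric models are pooled into a single
Benjamini–Hochberg FDR family by default (the conservative reading of
"adjusted across models"); a per-model family is a config option. Cohen's d
per state is computed from covariate-residualized raw values with the
pooled-SD (n−1 weighted) formula.

### Brain–behaviour PLSC

Partial least squares correlation links a behaviour block (perceived stress,
childhood trauma, alpha-amylase, cortisol awakening response AUC_I) to a
brain block (entries and occurrence of the group-differing CAPs). Columns
are z-scored within group (the grouped-toolbox convention), the per-group
cross-correlation blocks are stacked, and the stacked matrix is decomposed
by SVD; behaviour saliences are group-blocked, all saliences are unit-norm,
and with standardized data they read like correlation coefficients. The SVD
sign ambiguity is resolved by forcing the first non-zero behaviour salience
of each component positive. Component significance uses permutation testing
(behaviour rows permuted within group; p = (1 + exceedances)/(n_perm + 1));
salience robustness uses bootstrap resampling of subjects within group with
per-resample sign alignment to the original solution, 5th–95th percentile
intervals, and a "stable" flag when the interval excludes zero. Subjects
with missing behaviour cells are dropped listwise from the PLSC only, never
from the group models.

AUC_I follows the trapezoid-minus-baseline convention on the five cortisol
samples at 0/15/30/45/60 minutes post-awakening: trapezoidal area minus
baseline × 60 min; it can be negative, and any missing sample makes the
subject's value undefined.

## The synthetic cohort generator

The generator emulates the study design the analysis expects: two groups of
30 subjects, 300 volumes at TR 1.3 s, and a brain of ~2000 "parcel-like"
voxels rather than a full acquisition grid (full NIfTI export is supported
but not the default). Its components:

- **States.** A first-order Markov chain over {baseline, state 1..K} with
  K = 3 by default. Control baseline row: stay 0.80, entries (0.09, 0.06,
  0.05); patient row: (0.05, 0.10, 0.05); state rows dwell at 0.55. Patients
  therefore enter state 1 less and state 2 more — the planted group
  difference. One state is active per volume, keeping ground-truth labels
  unambiguous. The chain starts from its stationary distribution.
- **Signal.** Active volumes carry the state's template (random unit-norm
  map, rendered at per-voxel RMS 1) plus a seed amplitude (gain 1.0 on the
  seed voxels), a per-voxel linear/quadratic drift (SD 0.3), and Gaussian
  noise with SD 1/snr (snr = 2 by default, giving per-frame frame–template
  spatial correlation snr/√(snr²+1) ≈ 0.89). The seed occupies 1.5 % of
  voxels (30/2000), deliberately small relative to the brain so that global
  signal regression does not absorb the seed signal; scaled-down validation
  cohorts keep the seed at 2 % for the same reason.
- **Motion.** A smooth random walk (0.02 mm / 2·10⁻⁴ rad per step) plus
  step-change spikes at rate 0.02 per volume, sized to guarantee FD > 0.5 mm
  at spiked volumes.
- **Behaviour.** Each subject has a latent score s ~ N(0,1). In patients
  only, s modulates the transition matrix (entry into state 1 down, state 2
  up, gain 0.35) and the designated stress measures: perceived stress and
  the cortisol-bump amplitude equal 0.5·s + noise (so they correlate with s
  at r = 0.5); childhood trauma and alpha-amylase get group-specific means
  but no latent link, mirroring a battery in which only part of the stress
  measures tracks current HPA-axis load. Controls' behaviour is independent
  of their dynamics. Scalar columns are scaled to the group means/SDs of the
  emulated study population; cortisol curves are baseline + a rise-and-fall
  bump peaking at 30 min whose amplitude carries the latent signal (only
  AUC_I is consumed downstream, so the exact bump shape is free). Sex is
  drawn at the study's 24F/6M ratio; menstrual-cycle covariates are not
  simulated (the residualizer is covariate-agnostic).

What the generator does **not** emulate: hemodynamic convolution, spatial
autocorrelation and smoothing, scanner physics, tissue compartments (white
matter / CSF regressors are supported by the cleaning API but not generated),
state mixtures, and non-Gaussian seed noise. Passing the validation suite
therefore shows that the pipeline recovers the structure this model plants
at realistic sizes and noise levels — not that it is robust to every
property of real fMRI.

## Validation studies and problem sizes

The built-in studies (`capdyn.validation`, also run by
`scripts/acceptance.py`) use these sizes, chosen to make a desktop run
practical while keeping estimates stable:

- threshold calibration: 100 subjects × 300 volumes of standard-normal seed
  series (binomial SE ≈ 0.002 at n = 30 000);
- consensus K selection: 20 repeats of a 12-subject reference group on 400
  voxels, k_range 2–5, 100 resamples per K (the analysis default; fewer
  resamples make the PAC estimate noisy enough to mis-resolve near-ties);
- map recovery / assignment accuracy / occupancy recovery / reference
  self-consistency: one full 30+30 cohort at snr 2 (the default spec);
- contrast calibration: 500 null cohorts of 20+20 subjects (metrics taken
  from planted label sequences directly, isolating the statistical model);
  sign recovery: 20 replicate 30+30 cohorts;
- PLSC: 1000 null simulations and 20 power replicates at the study's 27+30
  with 200 permutations (scaled down from the analysis default of 2000). The
  power study plants the r = 0.5 cross-block link directly (every behaviour
  and brain column loads on a shared patient-only factor). A second,
  stricter study routes the link through the latent-modulated dynamics
  instead; there the effective behaviour–brain correlation is the product of
  the behaviour link (0.5) and the latent-to-metric correlation (~0.6),
  i.e. ~0.3, and detection power is correspondingly lower — both numbers are
  reported by the acceptance script.

## Numerical decisions

- All randomness flows through `numpy` `SeedSequence` spawning; identical
  (config, seed) pairs give byte-identical outputs, and per-stage seeds are
  derived independently so changing, e.g., the permutation count never
  changes CAP maps or metrics.
- Percentiles use linear interpolation (`numpy.percentile`).
- PAC ties break to the smaller K; pairs never co-selected during consensus
  resampling have undefined consensus and are excluded from PAC (logged).
- k-means never returns empty clusters with scikit-learn's relocation, but a
  5-attempt retry guards the contract; cluster renumbering ties break by
  first occurrence.
- Zero-variance frames cannot be correlated and are left unassigned with a
  warning; zero-variance behaviour columns abort a PLSC fit with the column
  named; bootstrap resamples that produce one are redrawn (≤ 10 tries, then
  an NA draw).
- Collinear design columns (nuisance regression, residualization) are
  dropped greedily left-to-right with a warning rather than failing.
- Nuisance regression and high-pass are applied sequentially in that order
  (the joint single-model variant is a possible extension).

## Known limitations

- The permutation scheme permutes behaviour rows within group; permuting
  across groups is a config variant, not the default.
- The mixed model's random intercept cannot represent the negative
  between-state correlation that compositional metrics induce; the
  cluster-robust contrasts are the guard, not a cure.
- Consensus clustering cost grows with the square of the pooled frame count;
  the implementation is dense and intended for cohort-scale (≲ several
  thousand frames) inputs.
- No whole-brain (seed-free) CAP variant, no co-deactivation CAP sets beyond
  the symmetric-threshold config flag, no transition-probability matrices
  between CAPs, and no spatial registration: inputs are assumed
  spatially preprocessed and in a common space.
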