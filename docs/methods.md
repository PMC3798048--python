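# Methods

`causalbold` implements a complete effective-connectivity classification
analysis for ROI-level task fMRI: blind hemodynamic deconvolution,
multivariate autoregressive (MVAR) Granger-causality estimation,
recursive cluster elimination SVM (RCE-SVM) classification with exact
binomial significance, and a motion/SNR quality-control layer.  Because
studies of this design rarely deposit raw data, the package includes a
first-class synthetic cohort generator that reproduces the statistical
structure the analysis assumes, so every stage is testable end to end.

## Synthetic cohort model

**Neuronal dynamics.** Each subject's latent neuronal activity is a
stable lag-1 linear recursion on a fine grid (`dt = TR/10`, TR = 1 s):

    h_t = W h_{t-1} + g u_t + w_t,   w_t ~ N(0, σ_n² I)

with `W` the subject's directed coupling matrix, `u` the task boxcar and
`g` the stimulus gain.  A first-order process on the fine grid matches
the first-order MVAR fitted downstream, keeping coefficient recovery
directly checkable.  Defaults: diagonal self-coupling 0.8 (a ~0.5 s
neuronal time constant), innovation s.d. 0.1, gain 0.15 (evoked plateau
≈ 0.75, i.e. evoked activity several times the background fluctuation —
typical of robust task responses).  A 200-step burn-in is discarded.

**Group structure.** Two group-level matrices share a sparse random
background (15% of directed pairs, weights ~N(0, 0.04)) and differ only
on `n_discriminative_paths` designated directed paths (default 19),
where the TD weight exceeds the ASD weight by
`effect_size × path_weight_sd` around a shared baseline of 0.10.  The
designated paths respect a random feed-forward hierarchy: an acyclic set
of strong paths adds nothing to the spectral radius, so the group
difference never trades off against stationarity.  If a configuration
still destabilizes the recursion, both matrices are shrunk by a common
off-diagonal factor (warned), preserving group equality off the
designated paths.  Subjects draw individual matrices around their group
matrix: jitter s.d. `path_weight_sd` (default 0.06) on active entries —
this is the "within-group spread" entering the effect-size definition —
and one sixth of that elsewhere.

**Hemodynamics and noise.** The latent series drives a
balloon–Windkessel forward model (below) with per-subject/ROI
hemodynamic parameters jittered log-normally (fractional s.d.
`hrf_jitter`, default 0.1).  BOLD is read out at the end of each TR and
white noise is added with variance `var(clean)/(snr_target − 1)`, so the
variance-ratio SNR (total/noise) sits at `snr_target` (default 2, the
usual task-fMRI regime).

**Behaviour scores and FA.** AQ and RME have uniform marginals over
4–38 and 15–24 and couple to the subject's mean designated-path weight
through a Gaussian copula (AQ negatively, RME positively).  The default
copula correlation is 0.3: the mean weight aggregates the group effect
across all 19 paths, so even this modest coupling yields clear
behaviour–connectivity correlations at n = 30, while keeping the scores
weaker classification features than the individual paths — matching the
qualitative finding this design emulates, where every top-ranked
classification feature was a connectivity path and the scores only
correlated with them.  FA is uniform on [0.30, 0.60] with a group shift
of `0.01 × effect_size` (ASD lower); tying the shift to the effect size
makes a zero-effect cohort exchangeable on *every* feature, which the
null-calibration checks require.

**Motion.** Six rigid-body parameters follow mean-reverting AR(1) walks
(stationary s.d. `magnitude/2`, lag-1 coefficient 0.95) started at zero
(volumes are realigned to the first frame).  At the default magnitude
0.2 mm the 0.5 mm screening threshold is exceeded in well under 5% of
subjects.  Motion is label-independent: group differences in motion are
sampling noise by construction, so motion QC should come out clean.

**What the generator does not emulate.** No voxel-level structure, no
physiological (cardiac/respiratory) noise spectra, no scanner drift, no
motion–signal coupling (head motion does not corrupt the BOLD series),
no nonlinear neuronal dynamics, and FA is a scalar stand-in rather than
a tractography product.  Passing tests therefore demonstrate that the
analysis recovers the structures it assumes, under noise levels it
states — not that those assumptions hold in real data.

## Balloon model and blind deconvolution

The forward model is the standard balloon–Windkessel system — neuronal
drive `h` → vasodilatory signal `s` → inflow `f` → venous volume `v` and
deoxyhemoglobin `q` — with the classical nonlinear BOLD readout

    y = V0 [k1 (1 − q) + k2 (1 − q/v) + k3 (1 − v)],
    k1 = 7 E0, k2 = 2, k3 = 2 E0 − 0.2, V0 = 0.04,

zero at rest.  Five parameters (signal decay κ = 0.65 s⁻¹, feedback
γ = 0.41 s⁻¹, transit time τ = 0.98 s, stiffness α = 0.32, resting
oxygen extraction E₀ = 0.34) with Euler integration at `dt = TR/10`.
Flow/volume/deoxyhemoglobin are floored at a small positive value with a
warning if a step undershoots.

Deconvolution runs a square-root cubature Kalman filter over the
augmented state `[h, s, f, v, q, log θ]` (third-degree spherical-radial
cubature points, QR-based square-root propagation), with measurement
updates at each TR, followed by a Rauch–Tung–Striebel-type cubature
smoother; the filter–smoother pass can be iterated with the re-estimated
parameters as the new prior (`n_iterations`, default 1 — the smoother
already uses all data, and a second pass changed recovery correlations
by < 0.01 in our simulations).  Parameters are estimated jointly by
state augmentation as slow random walks on the log scale (positivity by
construction), prior spread 0.2 log-units.  The neuronal prior inside
the filter is an Ornstein–Uhlenbeck process (decay 1 s⁻¹) driven by the
known boxcar with gain 1; process-noise defaults (per fine step): 0.1 on
`h`, 1e-3 on the physiological states, 5e-4 on log-parameters.  The
measurement-noise variance defaults to `var(diff(y))/2`, a robust
estimate when the clean signal is smooth at the TR scale.  The smoothed
neuronal mean is the deconvolved series (10× the acquisition
resolution); innovation diagnostics (normalized innovation squared)
are returned for filter-consistency checks.  Exogenous timing enters the
filter as a known input rather than as an estimated state: it is
observed, and estimating it would only inflate the state covariance.

At SNR 2 with hemodynamic parameters jittered 10% per seed, the
smoothed estimate correlates with the true neuronal series at median
r ≈ 0.87 over 20 seeds (the acceptance suite asserts r ≥ 0.7).

## MVAR connectivity

For `l` series the model couples a zero-diagonal instantaneous matrix
`a(0)` with lagged matrices `a(1..p)`; including the zero-lag term keeps
instantaneous correlation from leaking into the lagged (Granger-causal)
coefficients.  Estimation is per-target ordinary least squares on all
regressors jointly; the estimability precondition `k²p < T` is enforced
(324 < 460 for the 18-ROI, first-order study model).  `p = 1` is the
pipeline default; `select_model_order` (BIC default, common-sample
evaluation) is available as a utility.  Directed features are the lag-1
coefficients `a_sink,source(1)`, named `SRC->SNK`, 306 for 18 ROIs;
self-paths are excluded and `a(0)` is retained in the model but not
exported as features.  Functional connectivity is the Fisher-z Pearson
correlation per unordered pair on the TR-grid BOLD (153 pairs), with
|r| clamped at 1 − 1e-12 to keep z finite.

The per-equation joint least-squares fit treats the instantaneous terms
as ordinary regressors; a simultaneous-equation model with a(0) on both
sides is not separately identified, which is accepted here as the
descriptive convention (the instantaneous matrix is not exported).

One deliberate normalization choice: the pipeline fits the MVAR on the
*raw* latent (or deconvolved) series rather than z-scoring each ROI
first.  Per-ROI variance normalization multiplies the lag-1 coefficients
by subject-specific variance ratios; on synthetic cohorts this inflates
the within-group spread of the path features and dilutes the designed
group effect from d ≈ 1.4 to d ≈ 0.9.  Variance normalization exists to
remove arbitrary scanner gain from raw fMRI units; synthetic series (and
model-based deconvolution output) are already on a consistent scale, so
the default is off (`normalize_series` restores it).

## RCE-SVM classification

Per stratified 80/20 train/test split (default 50 splits): features are
standardized with training statistics only; k-means clusters the
features (points in training-subject space), the initial cluster count
starting at the feature count and decreasing until no cluster is empty;
each cluster is scored by the mean held-out accuracy of a linear SVM
(C = 1) over 10 stratified folds × `n_reps` repetitions (partitions are
shared across clusters within a loop, so scores are comparable); the
lowest-scoring ⌈10%⌉ of clusters are eliminated (ties remove the
smaller index); the cluster count falls to max(2, ⌊0.9 n⌋) and the loop
repeats until two clusters remain.  Test accuracy per loop comes from an
SVM trained on the full training split with the surviving features —
with a deterministic classifier the mean over scoring repetitions equals
this single value.  Loops are aligned across splits from the final loop
backwards (every split terminates at two clusters) and averaged; each
loop's mean accuracy gets an exact binomial tail p-value against
B(η = subjects, ρ = 0.5) with successes = round(accuracy·η) — this
convention reproduces all 23 published accuracy→p rows exactly — and a
Bonferroni correction over the number of loops.  Consensus survivors are
features present in the final loop of at least half the splits, ranked
by presence then mean final cluster score.

A structural property worth knowing: with all-distinct feature vectors,
k-means at n = feature-count yields singleton clusters, and
n − ⌈n/10⌉ = ⌊0.9n⌋ keeps the cluster count exactly equal to the
feature count in every loop, so each split's final loop carries exactly
two features.  Correlated real-world features that collapse into fewer
initial clusters would carry multi-feature clusters to the end instead;
synthetic continuous features do not collapse.  Consequently the
classifier's accuracy trajectory peaks around 5–10 surviving features
and dips at the 2-feature final loop (two features with per-path
standardized effect 1.5 support at most ≈ Φ(1.5·√2/2) ≈ 0.855 expected
accuracy).  The acceptance suite measures the final loop as defined.

The inner-loop SVM is a dual coordinate-descent solver (Hsieh et al.
2008 algorithm; bias as an augmented feature; deterministic sweep
order), JIT-compiled so the ~10⁵ tiny fits of a full run stay fast; its
decision boundaries are cross-checked against `sklearn.svm.SVC
(kernel="linear")` in the test suite (≈97% test-prediction agreement on
random tiny problems, differences confined to near-boundary points).

## QC and group statistics

Framewise displacement: backward differences of the six parameters,
rotations converted degrees → radians → arc length on a 50 mm sphere;
the first frame is defined as 0.  FD is invariant to constant offsets
and its rotational part scales linearly with the radius.  RMS motion is
computed per parameter.  No scrubbing is applied anywhere — Granger
causality is sensitive to temporal ordering, and removing frames would
create artificial discontinuities.

Mann–Whitney U uses the min-U convention with midrank ties and a
tie-corrected, continuity-corrected normal z (reported non-positive, as
is conventional with min-U); the exact distribution is used for small
untied samples.  Spearman correlation uses midrank ties with a
t-approximation p, or exhaustive permutation for n ≤ 9.  Both match
brute-force enumeration oracles in the tests.  The deconvolved-series
SNR is var(entire series)/var(non-stimulation samples); group SNR
comparison uses the Wilcoxon rank-sum (same statistic family as U).
Two-sample t from printed summaries is |Δmean|/√(se₁² + se₂²), which
equals the pooled equal-n t.  Per-path group comparisons are two-sample
t tests with a configurable Bonferroni count (default 18 when 19 paths
are tested — one path is conventionally reported uncorrected).

## Pipeline, formats, determinism

`run_pipeline` chains simulate → (deconvolve | latent truth) → MVAR →
feature assembly (306 + 153 + AQ + RME + FA = 462 columns) → RCE-SVM →
QC screen → report.  The motion screen excludes (and logs) subjects
whose any-parameter excursion exceeds 0.5 mm/deg.  Time series are TSV
(columns = canonical ROI labels), motion traces are SPM rp-style
six-column text (rotations in radians on disk, degrees in memory),
feature tables CSV, results JSON, configs YAML.  Every stage derives its
randomness from the single pipeline seed through independent
`SeedSequence` streams; identical configurations reproduce identical
reports, and every report embeds the config hash and seed.

## Problem sizes used in the automated checks

Unit tests run on reduced cohorts (4–6 ROIs, 100–200 volumes).  The
acceptance suite uses the full study dimensions — 30 subjects, 18 ROIs,
460 volumes, 462 features, 19 designated paths, effect size 1.5 —
with 5 train/test splits and 15 scoring repetitions per seed over
10 seeds (the procedure is unchanged; only the split/repetition counts
are reduced), and 20 seeds for the deconvolution-recovery check.

## Known limitations

- Blind deconvolution leaves a per-ROI amplitude indeterminacy when
  hemodynamic parameters vary; downstream coefficients inherit a small
  multiplicative uncertainty.
- The RCE-SVM final loop's two-feature ceiling (above) bounds the
  terminal accuracy on synthetic cohorts below what multi-feature final
  clusters would achieve on strongly correlated real features.
- The binomial significance recipe is anti-conservative under this
  feature-selection regime: with 462 features and 30 subjects, roughly
  one null cohort in six contains a feature whose realized group
  separation reaches |d| ≈ 1.5 purely by sampling (per-feature d̂ has
  t(28)-scale tails).  Such a cohort-level fluke separates every
  split's held-out subjects — train/test splitting protects against
  split-level overfitting, not against cohort-level luck — and pushes
  some loop's mean accuracy past the Bonferroni-corrected binomial
  threshold.  Group-label permutation would give a calibrated null;
  the binomial convention is retained because it is the analysis this
  package implements, and its false-positive behaviour is measured by
  the null-cohort acceptance test.
- The exact-permutation Spearman mode enumerates n! permutations and is
  restricted to n ≤ 9.
- Euler integration of the balloon system is first-order; the fine grid
  (0.1 s) keeps the discretization error far below measurement noise,
  but stiff parameter draws outside the jitter range used here would
  warrant a smaller step.
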