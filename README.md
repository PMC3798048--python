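# causalbold

Effective-connectivity classification for ROI-level task fMRI: blind
hemodynamic deconvolution, multivariate autoregressive (MVAR) Granger
causality, and recursive cluster elimination SVM (RCE-SVM) — with a
synthetic cohort generator so the whole chain runs, and is tested,
without any imaging data.

## The problem

Directed ("effective") connectivity between brain regions — who drives
whom, not merely who co-fluctuates — is a candidate imaging signature
for neuropsychiatric conditions such as autism.  Estimating it from
BOLD fMRI faces three obstacles this package addresses in sequence:

1. **The hemodynamic response hides the neuronal signal.**  BOLD is a
   slow, regionally variable blur of neuronal activity.  A square-root
   cubature Kalman filter/smoother jointly estimates the hidden
   neuronal series `h` and the balloon-model parameters θ from the
   state-space model

       x̃ = [h, s, f, v, q, θ],   y_t = m(x̃_t) + ε_t,

   returning `h` at ten times the acquisition resolution
   (`causalbold.hemodynamics`).

2. **Directed influence must be separated from instantaneous
   correlation.**  The deconvolved series enter an MVAR model with an
   instantaneous term,

       h(t) = a(0) h(t) + Σ_{j=1..p} a(j) h(t−j) + e(t),

   where `a(0)` (zero diagonal) absorbs zero-lag correlation and the
   lagged `a(j)` carry the Granger-causal path weights; a first-order
   model over 18 ROIs has k²p = 324 coefficients, estimable from 460
   volumes (`causalbold.mvar`).

3. **A high-dimensional feature set must predict group membership of
   unseen subjects.**  306 directed path weights, 153 Fisher-z
   functional-connectivity scores, AQ and RME behaviour scores, and one
   FA value (462 features for 30 subjects) enter the RCE-SVM: k-means
   clusters the features, each cluster is scored by 10-fold × 50-rep
   linear-SVM cross-validation on the training subjects, the worst 10%
   of clusters are eliminated, and the loop repeats down to two
   clusters.  Loop accuracies are tested against an exact binomial null
   B(η, 0.5) with Bonferroni correction (`causalbold.rce`).

A QC layer (`causalbold.qc`) provides RMS motion, framewise
displacement (rotations as arc length on a 50 mm sphere), variance-ratio
SNR of deconvolved series, Mann–Whitney U / Wilcoxon rank-sum, Spearman
correlations with an exact small-n mode, and Bonferroni-corrected
per-path group comparisons.

Because the data for such a study are typically not deposited, the
package ships a generator (`causalbold.cohort`) producing cohorts with a
known ground-truth directed network: group differences on designated
paths, balloon hemodynamics with HRF variability, task-SNR noise, motion
traces, and behaviour scores coupled to path strength.  Ground truth is
retained on every synthetic subject, so recovery can be measured.

## A worked example

```python
import numpy as np
from causalbold import (CohortConfig, CkfConfig, balloon_forward,
                        ckf_deconvolve, generate_boxcar)
from causalbold.cohort import default_event_schedule, simulate_neuronal_series
from causalbold.hemodynamics import HemodynamicParams

config = CohortConfig(n_rois=1, n_volumes=460, seed=3, n_discriminative_paths=0)
rng = np.random.default_rng(3)
u = generate_boxcar(default_event_schedule(config, rng), 460.0, dt=0.1)
h = simulate_neuronal_series(np.array([[0.8]]), u, config, rng)[0]

clean = balloon_forward(h, HemodynamicParams(), dt=0.1, tr=1.0)
bold = clean + rng.normal(0, clean.std(), size=clean.shape)   # SNR = 2

result = ckf_deconvolve(bold, u, CkfConfig())
print(len(result.neuronal_estimate))                       # 4600
print(round(np.corrcoef(result.neuronal_estimate, h)[0, 1], 3))  # 0.869
```

The deconvolved series has 4600 samples (ten per TR) and correlates with
the hidden neuronal truth at r = 0.869 despite the BOLD series carrying
as much noise variance as signal — accurate enough that lag-1 causal
structure fitted on it is recoverable.  The `examples/` directory walks
through each capability the same way: cohort simulation, deconvolution,
connectivity fitting, RCE-SVM classification, QC statistics, and the
one-call pipeline (`run_pipeline`), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the pipeline stages for shell use:

```bash
causalbold simulate --seed 1 --out cohort/
causalbold classify --features features.csv --seed 1 --out rce/
causalbold run-all --seed 1 --out run/
```

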