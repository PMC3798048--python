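"""Blind hemodynamic deconvolution of one ROI's BOLD series.

A known neuronal series drives the balloon model; white noise is added at
variance-ratio SNR 2; the cubature Kalman filter/smoother then estimates
the hidden neuronal series (at 10x the acquisition resolution) without
knowing the hemodynamic parameters.
"""

import numpy as np

from causalbold import (
    CkfConfig,
    CohortConfig,
    HemodynamicParams,
    balloon_forward,
    ckf_deconvolve,
    generate_boxcar,
)
from causalbold.cohort import default_event_schedule, simulate_neuronal_series

config = CohortConfig(n_rois=1, n_volumes=460, seed=3, n_discriminative_paths=0)
rng = np.random.default_rng(3)
u = generate_boxcar(default_event_schedule(config, rng), 460.0, dt=0.1)
neuronal_truth = simulate_neuronal_series(np.array([[0.8]]), u, config, rng)[0]

params = HemodynamicParams()  # classical balloon-model values
clean = balloon_forward(neuronal_truth, params, dt=0.1, tr=1.0)
bold = clean + rng.normal(0, clean.std(), size=clean.shape)  # SNR = 2

result = ckf_deconvolve(bold, u, CkfConfig())
r = np.corrcoef(result.neuronal_estimate, neuronal_truth)[0, 1]

print(f"observed BOLD volumes:   {len(bold)}")
print(f"neuronal estimate steps: {len(result.neuronal_estimate)} (10x upsampled)")
print(f"Pearson r(estimate, truth) = {r:.3f}")
print("-> above ~0.7 the lag-1 causal structure survives deconvolution")
print(f"mean normalized innovation^2 = "
      f"{result.innovation_diagnostics['mean_nis']:.2f} (O(1) = filter consistent)")
p = result.params_estimate
print(f"estimated hemodynamics: signal decay {float(p.signal_decay):.2f}/s, "
      f"transit {float(p.transit_time):.2f}s, E0 {float(p.oxygen_extraction):.2f}")
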