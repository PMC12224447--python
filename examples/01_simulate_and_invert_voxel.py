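"""Simulate one dual-echo bolus voxel and invert it back to relaxation rates.

Builds a ground-truth voxel whose spin echo peaks 0.4 s before the
gradient echo, generates the signal pair, recovers the relaxation-rate
curves and fits the gamma-variate model to each echo.
"""

import numpy as np

import vamkit as vk

acq = vk.AcquisitionParams()  # TR 1.5 s, TE 22/90 ms, 10 baseline frames
truth = vk.VoxelTruth(amplitude_ge=20.0, amplitude_se=4.0,
                      ttp_ge=26.0, ttp_se=25.6, noise_sd=0.0)

signal_ge, signal_se = vk.simulate_voxel(truth, acq)

for name, signal, te, true_ttp in [("GE", signal_ge, acq.te_ge, truth.ttp_ge),
                                   ("SE", signal_se, acq.te_se, truth.ttp_se)]:
    s0 = vk.estimate_baseline(signal, acq.n_baseline)
    delta_r = vk.compute_delta_r(signal, s0, te)
    fit = vk.fit_gamma_variate(delta_r, acq.times)
    print(f"{name}: S0 = {s0:7.1f}  peak dR = {np.max(delta_r):5.2f} 1/s  "
          f"fitted ttp = {fit.ttp:6.3f} s (truth {true_ttp}; r2 = {fit.r2:.4f})")

# The fitted times-to-peak are continuous quantities: although frames are
# 1.5 s apart, the 0.4 s echo-time offset is recovered almost exactly.
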