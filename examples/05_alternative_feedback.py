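"""Alternative negative-feedback models: global inhibition and
short-term depression.

Neither reproduces the post-learning rebound: shared slow inhibition
leaves the overlap equation first-order (no overshoot), and the
best-fit depression model rings only weakly.
"""

import numpy as np

from famdyn import (DriveWaveform, GlobalInhibitionParams, fit_std_params,
                    presets, simulate_global_inhibition, simulate_std_reduced)
from famdyn.inference import _std_trace_on_data_grid

fig5 = presets.fig5_meanfield_params()

gi = GlobalInhibitionParams(fgbar_R=0.9, adapt_strength=1.8,
                            drive_m=fig5.drive_m, dt=0.5)
traj = simulate_global_inhibition(gi, 800.0)
m = traj.m[np.argmax(traj.m):]
rebounds = int(np.sum((m[1:-1] > m[:-2]) & (m[1:-1] > m[2:])))
print(f"global inhibition: local maxima after the peak = {rebounds}")

# reduced STD model at its reference strengths, then re-fitted from the
# traces alone (synthetic stand-in for the top-rank data traces)
n_bins, dt = 44, 5.0
wave = DriveWaveform(1, 1, 150, 50)
drive = 6.0 / wave(75 * np.log(3)) * wave(np.arange(n_bins) * dt)
novel_max = np.zeros(n_bins)
novel_max[1:] = drive[:-1]
familiar_max = _std_trace_on_data_grid(2.56, 0.125, novel_max[1:],
                                       novel_max[0], 5.0, 200.0, dt)
fit = fit_std_params(novel_max, familiar_max, dt=dt)
print(f"STD fit: fg = {fit.fg_strength:.3f} (truth 2.56), "
      f"gamma = {fit.depletion_strength:.4f} (truth 0.125)")

_, r, _ = simulate_std_reduced(fit.fg_strength, fit.depletion_strength,
                               200.0, lambda t: 6.0 / wave(75 * np.log(3)) * wave(t),
                               600.0)
i_pk = int(np.argmax(r))
i_tr = i_pk + int(np.argmin(r[i_pk:]))
print(f"STD rebound above trough: {r[i_tr:].max() - r[i_tr]:.4f} "
      f"(first peak {r[i_pk]:.2f})")
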