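# Reduced short-term-depression model fitted to top-rank traces.
std:
  tau_rate: 5.0             # ms
  tau_recover: 200.0        # ms (tau_x)
best_fit:                   # reported best fit to the familiar max response
  fg_strength: 2.56         # f_m^R g_m^R
  depletion_strength: 0.125 # gamma
fit_grid:
  fg_bounds: [0.1, 10.0]
  gamma_bounds: [0.001, 3.0]
  grid_size: 60
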