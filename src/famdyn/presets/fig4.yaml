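# Full-network simulation: Hebbian recurrent plasticity, uniform
# feedforward scaling, spike-frequency adaptation.
network:
  n_units: 2000
  recurrent_scale: 0.0      # w_R
  adapt_strength: 1.8       # k
  tau_rate: 5.0             # ms
  tau_adapt: 200.0          # ms
drive:
  tau_slow: 150.0           # ms (slow exponential of I_dyn)
  tau_fast: 50.0            # ms
  baseline_rate: 5.0        # rate units; I_const solves r* = 5
plasticity:
  hebbian_strength: 0.9     # alpha
  feedforward_gain: 0.4     # gamma (learned scaling of the dynamic input)
  selectivity_shape: 3.0    # gamma-distribution shape of xi
protocol:
  present_ms: 150.0         # P_1
  decay_ms: 100.0           # P_2 (linear decay of the previous drive)
  decay: linear
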