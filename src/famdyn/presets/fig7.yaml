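# Two-population competition: each population follows the learned
# m-dynamics; mutual inhibition w_c through a shifted-rectified transfer.
competition:
  mutual_inhibition: 0.1    # w_c
  fgbar_R: 0.9
  adapt_strength: 1.8       # k
  tau_rate: 5.0             # ms
  tau_adapt: 200.0          # ms
  transfer_threshold: -3.0  # Phi(x) = x for x >= -3, else 0
drive:                      # I_m,i = e^{-t/tau_slow} - e^{-t/tau_fast}
  tau_slow: 400.0
  tau_fast: 20.0
onsets: [0.0, 500.0]        # stimulus 2 arrives 500 ms after stimulus 1
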