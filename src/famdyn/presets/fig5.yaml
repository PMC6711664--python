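# Mean-field fit to dimming-detection population responses.
# Drive waveforms follow the convention a e^{-t/tau_slow} - b e^{-t/tau_fast} + (b - a).
meanfield:
  recurrent_scale: 0.0      # w_R
  adapt_strength: 1.8       # k
  tau_rate: 5.0             # ms
  tau_adapt: 200.0          # ms
  fgbar_R: 0.9
  fbar_R: 0.3
  fbar_F: -0.7
  fgbar_F: 0.0
drive_mean:                 # mean external input I_bar
  a: 6.0
  b: 5.0
  tau_slow: 700.0
  tau_fast: 40.0
drive_m:                    # external input of the m dynamics
  a: 5.0
  b: 5.0
  tau_slow: 400.0
  tau_fast: 20.0
drive_f: drive_m            # I_F shares the m-drive waveform
successive:
  present_ms: 150.0
  decay: exponential
  decay_ms: 50.0
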