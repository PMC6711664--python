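# Methods

## Scope and model

`famdyn` models the effect of stimulus familiarity on visual response
dynamics in inferotemporal cortex with an excitatory rate network:
firing rates `r_i` relax toward `Phi(total input)` with time constant
`tau_r`, and a low-pass-filtered copy of each rate (`a_i`, time
constant `tau_a`, gain `k`) is subtracted from the input —
spike-frequency adaptation as linear, private negative feedback.
Inhibition is not modeled explicitly; it is assumed to track the mean
excitatory rate instantaneously, which is why the effective uniform
recurrent weight `w_R` may be negative. Learning is a one-shot,
separable weight update `dW_ij = f(xi_i) g(xi_j)/N` applied between the
"novel" and "familiar" phases; there is no ongoing plasticity within a
trial.

Key parameter defaults (used throughout unless a preset says
otherwise): `tau_r = 5 ms`, `tau_a = 200 ms`, `k = 1.8`, `w_R = 0`.
These are the values obtained by fitting the reduced dynamics to
population responses from a dimming-detection experiment; the learned
feedback is `fg_R = <f_R g_R> = 0.9` with `<f_R> = 0.3` and
`<f_F> = -0.7` (net feedforward depression). Drive waveforms are
differences of exponentials `a e^{-t/tau_slow} - b e^{-t/tau_fast} +
(b - a)`; the mean-input waveform uses `a = 6, b = 5`, taus 700/40 ms,
and the overlap-input waveform `a = b = 5`, taus 400/20 ms.

## Mean-field reduction and regimes

With linear `Phi`, uniform pre-learning connectivity and zero-sum
pre-dependence `g`, averaging the network equations gives a closed
4-variable system in `(rbar, abar, m, n)`, where `m = <g(xi) r>` is the
overlap with the learned pattern. The reduction is exact, not
approximate: the equivalence test demands agreement with a 500-unit
network at 1e-6 relative (it is machine-precision in practice, since
both are stepped by the same explicit Euler rule).

The `(m, n)` block is classified by its eigenvalues, computed as
`(trace ± sqrt(disc))/2` from the 2×2 system matrix
`[[(-1+w)/tau_R, -k/tau_R], [1/tau_A, -1/tau_A]]`. The discriminant
`((-1+w)/tau_R + 1/tau_A)^2 - 4k/(tau_R tau_A)` defines the separatrix
between overshoot (stable node) and damped oscillation (stable focus);
stability additionally requires `w < 1 + tau_R/tau_A` and
`w - k - 1 < 0`. Boundary cases (`disc = 0`, marginal stability) are
labeled by the closed-set convention — node, stable — with the raw
discriminant and eigenvalues reported so callers can apply their own
tolerance. One printed form of the eigenvalue expression omits the ½
factor; the discriminant is the authoritative quantity and matches the
standard formula, which is what we implement (cross-checked against a
generic eigensolver).

The two-pulse (successive novel stimuli) constraint is evaluated on a
piecewise-linear caricature: linear rise to `r_0` over `t_0` (with
adaptation and input frozen), linear decay to `r_1` over `t_1`, with
`tau_eff = tau_R/(1 - w_R)`. The printed closed form for the second
peak is dimensionally inconsistent with its own substitution
`r_0 = I_0 t_0/tau_eff`; we implement
`(I_0 - a_1 k) t_0/tau_eff + r_1`, which reproduces the substitution
step, and validate the satisfied/violated flag against a fine Euler
integration of the same caricature (≥ 95% agreement away from the
boundary).

## Numerical integration

Explicit Euler with `dt = 0.5 ms` everywhere in simulation
(`dt <= tau_rate` is enforced; first-order convergence is verified by a
dt-halving test). The inference pipeline instead uses the coarse
discretization `tau_R = dt = 5 ms` deliberately, because it makes the
rate update `r(t+dt) = Phi(total input at t)` and hence input
reconstruction *exact* — the discretization is part of the method, not
an approximation of it. Negative rates are permitted under linear `Phi`
(the linearity assumption implies them; a clip-at-zero flag exists but
defaults off). Non-finite states abort with the first bad time step
named.

The reduced short-term-depression model is stiff at high rates (the
resource equation's effective rate `gamma * r` reaches ~0.75/ms), so it
is integrated at a 0.25 ms internal step with the binned drive held
constant within each 5 ms data bin, and sampled back onto the data
grid. Stepping it at the 5 ms data resolution would be unstable.

## Inference pipeline

Normalization follows the experimental procedure: per neuron, each
stimulus's response is time-averaged over 80–200 ms post-onset; the
mean and SD of those averages across *novel* stimuli z-score all of
that neuron's rates; stimuli are rank-ordered per neuron and condition
by time-averaged activity (stable sort, first-occurrence tie-break);
normalized traces are averaged across neurons at each rank. The SD is
the population (ddof = 0) standard deviation. Windows are inclusive of
both endpoints.

Input reconstruction and fitting use `w_R = 0`, `k = 1.8`,
`tau_A = 200 ms` by default. Adaptation is the Euler low-pass of the
measured trace with `a(0) = r(0)` (steady baseline). The pre-dependence
is one-hot on the top rank, so the overlap drive during fitting is the
*measured* top-rank familiar trace (teacher forcing) — this prevents
fitting error in the top-rank trace from propagating through the
network — and the feedforward regressor is the reconstructed top-rank
input. Each rank is an independent 2-unknown weighted least-squares
problem over the T−1 usable bins; bins at ≥ 230 ms carry weight 5 to
pin the rebound (for a consistent, noise-free system the weights are
irrelevant, which is tested). The overlap convention here drops the 1/N
factor (with one-hot `g`, `m` *is* the top-rank trace); the mean-field
module's 1/N convention differs by a constant that is absorbed into the
fitted coefficients.

The nonlinear transfer option tabulates `Phi` by quantile matching:
rank *i*'s time-averaged novel response (75–200 ms window) is paired
with the standard-normal quantile at probability `(i - 0.5)/n`. The
Gaussian's mean/SD are not identifiable from this construction, so a
standard normal is used and any affine freedom is absorbed into the
table; rate-order violations are cleaned by isotonic regression, and
inversion uses monotone piecewise-linear interpolation with linear
extrapolation beyond the table.

The short-term-depression fit minimizes the SSE between the reduced
model's response to the reconstructed novel-max input and the familiar
max trace, over `(fg, gamma)`: a fixed 60×60 log-spaced grid
(`fg` in [0.1, 10], `gamma` in [1e-3, 3]) followed by Nelder–Mead from
the grid optimum in log-parameters. Fully deterministic. Unstable
parameter combinations get infinite loss.

## Synthetic data generator

The generator emulates the passive-viewing layout — 125 rank-ordered
stimuli × 44 bins at 5 ms, z-scored units — by running the *same*
discrete forward model the inference inverts, with known ground truth.
Defaults define the study conditions and are not tuning knobs:

- Ground truth `f_R` rank-increasing from −0.3 to 0.9 (mean 0.3, top
  value 0.9) and `f_F` from −1.1 to −0.3 (mean −0.7), mirroring the
  population-fit coefficients.
- Per-rank drive amplitudes at Gaussian quantiles, `N(2, 1.5²)`,
  consistent with the Gaussian-input assumption of the transfer
  derivation; shared waveform is a peak-normalized difference of
  exponentials (150/50 ms).
- Observation noise (default SD 0.1 rate units) is iid Gaussian added
  after the dynamics, matching the treatment of trial-averaged rates;
  there is no process noise and no spike-count (Poisson) noise.

Because the familiar top rank drives itself only through its value at
the *previous* bin under the `tau_R = dt` update, the joint update over
ranks is explicit; no per-bin fixed-point iteration is needed.

What passing tests show, and what they do not: exact noise-free
recovery certifies the algebraic consistency of the forward and inverse
models; noisy recovery certifies robustness to observation noise of the
assumed kind. Neither certifies robustness to model mismatch present in
real recordings — trial-to-trial drive variability, non-Gaussian noise,
violations of the shared-rule-across-neurons assumption, or rank
instability across conditions.

## Protocol conventions

- Successive presentation: each stimulus's waveform restarts at its
  onset; the previous stimulus's drive decays linearly over `P_2`
  (network protocol) or exponentially with a 50 ms constant
  (mean-field protocol). Second-stimulus responses are compared as
  *evoked* peaks — peak minus the trace value at that stimulus's onset
  — because the learned assembly's oscillation can be in a negative
  trough at the second onset, which would contaminate raw peak ratios;
  the evoked measure isolates the response to the new stimulus.
- Competition: two populations, each following the learned overlap
  dynamics with its own adaptation, coupled by `-w_c m_j`
  (`w_c = 0.1`) through the literal shifted-rectified transfer
  `Phi(x) = x for x >= -3, else 0` (which admits negative outputs on
  [−3, 0)). Population 2's state is frozen at zero until its onset
  (the "silent before its stimulus" assumption, implemented as a state
  clamp); both populations start at 0.
- The `I_F` drive of the mean-field model shares the overlap-drive
  waveform: the fitted parameter list pins `<f_F>` but no separate
  waveform, and `fg_F` is set to 0 (absorbed into the fitted overlap
  drive).
- The baseline input of the full-network preset is solved from the
  closed-form fixed point `r* = I/(1 - w_R + k)` for a baseline rate
  of 5, not hand-tuned.

## Problem sizes

Defaults used by the test suite and examples: 125 × 44 surrogates for
inference; 500 units for the mean-field equivalence check; 2000 units
for the full-network demonstration; 200 random draws for the
regime-oracle and resource-positivity property tests. These sizes keep
every check well-resolved while remaining quick on a single CPU.

## Known limitations

- Units are abstract "rate units": the experimental convention mixes
  z-scored and Hz scales, and the model inherits that ambiguity.
- The linear-transfer assumption makes negative rates meaningful;
  results near the rectification threshold of the tabulated transfer
  depend on extrapolation.
- Only post-synaptic dependences are identifiable from single-cell
  data; the pre-dependence is assumed (one-hot on the top rank for
  inference, zero-sum for the reduction).
- The feedforward update as printed lacks the 1/N factor of the
  recurrent update; the package follows that convention
  (`normalize_by_n` defaults: on for recurrent, off for feedforward)
  and exposes the flag.
- Whether the 44 data bins start at stimulus onset is not fixed by the
  layout; `onset_index` is configurable and defaults to 0.
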