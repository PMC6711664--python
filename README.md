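# famdyn

Models of how visual familiarity reshapes response *dynamics* in
inferotemporal cortex (ITC), and a pipeline for inferring the synaptic
plasticity rule behind that reshaping from rank-ordered response time
courses.

When a monkey has seen a stimulus many times, ITC excitatory neurons
respond to it with a lower average rate, a higher peak in the most
selective cells, and a damped ~5–7 Hz oscillation ("rebound") that
novel stimuli do not evoke. `famdyn` implements the circuit model that
explains this — recurrent Hebbian potentiation interacting with slow
firing-rate adaptation — together with its mean-field reduction, the
analytic regime classification, two alternative negative-feedback
models (global inhibition, short-term depression), and the inference
machinery that reads the plasticity rule back out of data.

## The model

Rates `r_i` follow a standard adapting rate network,

    tau_r dr_i/dt = -r_i + Phi( sum_j W_ij r_j - k a_i + I_i(t) )
    tau_a da_i/dt = -a_i + r_i

with static transfer `Phi`, adaptation strength `k`, and external drive
`I_i(t)`. One-shot learning applies a separable update
`dW_ij = f(xi_i) g(xi_j) / N`, where `xi_i` is unit *i*'s time-averaged
response to the stimulus. With linear `Phi` and zero-sum `g`, the
network reduces exactly to four variables: the mean rate and its
adaptation `(rbar, abar)`, plus the overlap with the learned pattern
and its adaptation `(m, n)`. The learned `(m, n)` block is a 2-D linear
system whose eigenvalues

    lambda = (trace ± sqrt(disc))/2,
    disc = ((-1 + fg_R)/tau_R + 1/tau_A)^2 - 4 k/(tau_R tau_A)

cross from real (monotone decay) to complex (damped oscillation) as the
learned feedback `fg_R = <f_R g_R>` grows — familiarity literally moves
the circuit across the separatrix. At the fitted parameters
(`fg_R = 0.9, k = 1.8, tau_R = 5 ms, tau_A = 200 ms`) the period
`2*pi/Im(lambda)` is ≈ 150 ms.

The inference pipeline exploits the discretization `tau_R = dt = 5 ms`,
under which the rate update is invertible: external inputs are read off
the novel rank × time matrix exactly, and the per-rank post-synaptic
dependences `(f_R, f_F)` of recurrent and feedforward plasticity are
ordinary weighted least-squares solutions on the familiar matrix, with
the measured top-rank familiar trace as the overlap drive.

## Worked example

Generate a synthetic passive-viewing dataset (125 ranks × 44 bins at
5 ms) with known ground-truth plasticity, then recover it:

```python
import numpy as np
from scipy import stats
from famdyn import generate_surrogate_dataset, fit_postsynaptic_dependence

exact = generate_surrogate_dataset(noise_sd=0.0, seed=11)
res = fit_postsynaptic_dependence(exact.novel, exact.familiar)
print(np.abs(res.f_R - exact.truth_f_R).max())   # 3.33e-16

noisy = generate_surrogate_dataset(noise_sd=0.1, seed=12)
res_n = fit_postsynaptic_dependence(noisy.novel, noisy.familiar)
print(stats.spearmanr(noisy.truth_f_R, res_n.f_R).statistic)  # 0.9999
```

Noise-free recovery is exact to machine precision because the fitter
inverts the same discrete forward model the generator uses; with
observation noise of 0.1 rate units the rank ordering of the recurrent
dependence is essentially perfectly preserved (Spearman ρ ≈ 0.9999) and
the fitted means (`f_R` ≈ 0.30, `f_F` ≈ −0.68) reproduce the ground
truth (0.30, −0.70): net recurrent potentiation, net feedforward
depression.

The `examples/` directory holds one short script per capability
(regime analysis, mean-field protocols, the 2000-unit network,
inference, alternative feedback models, two-stimulus competition); each
prints the numbers it computes and says what they mean. The same
functionality is reachable from the shell:

```
famdyn classify-regime --fgbar 0.9 --k 1.8 --tau-r 5 --tau-a 200
famdyn generate-synthetic --noise 0.1 --seed 7 --out surr/
famdyn infer-plasticity --novel surr/novel.csv --familiar surr/familiar.csv --out fit.csv
```

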