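"""Surrogate datasets with the structure the inference pipeline assumes.

The generator emulates a passive-viewing dataset: 125 rank-ordered
stimuli x 44 time bins at 5 ms resolution, z-scored against novel
responses. Both conditions are produced by the same discrete forward
model the inference module inverts (tau_R = dt), with known
ground-truth post-synaptic dependences and iid Gaussian observation
noise added last — so noise-free recovery is exact by construction and
noisy recovery measures the pipeline's robustness, not model mismatch.

Per-rank external inputs are a shared difference-of-exponentials
waveform scaled by rank amplitudes placed at Gaussian quantiles,
matching the Gaussian-input assumption used when a nonlinear transfer
is derived from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .drives import DriveWaveform
from .inference import RankTimeMatrix
from .transfer import TransferFunction

__all__ = ["SurrogateDataset", "sample_selectivity", "generate_surrogate_dataset",
           "default_truth_f_R", "default_truth_f_F"]


@dataclass(frozen=True)
class SurrogateDataset:
    """Synthetic novel/familiar pair with known ground truth."""

    novel: RankTimeMatrix
    familiar: RankTimeMatrix
    truth_f_R: np.ndarray
    truth_f_F: np.ndarray
    inputs: np.ndarray            # per-rank drive I_i(t), all bins
    transfer: TransferFunction
    noise_sd: float
    seed: int


def sample_selectivity(n_units: int, shape: float = 3.0, scale: float = 1.0,
                       seed: int | None = None) -> np.ndarray:
    """iid gamma selectivity amplitudes xi_i (shape 3, unit scale)."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, scale, size=n_units)


def default_truth_f_R(n_ranks: int) -> np.ndarray:
    """Rank-increasing recurrent dependence, mean 0.3, top value 0.9 —
    potentiation concentrated in high-rate units."""
    return np.linspace(-0.3, 0.9, n_ranks)


def default_truth_f_F(n_ranks: int) -> np.ndarray:
    """Feedforward dependence with overall depression (mean -0.7)."""
    return np.linspace(-1.1, -0.3, n_ranks)


def _default_waveform() -> DriveWaveform:
    # peak-normalized difference of exponentials, 150/50 ms time constants
    w = DriveWaveform(amp_slow=1.0, amp_fast=1.0, tau_slow=150.0,
                      tau_fast=50.0)
    t_peak = np.log(150.0 / 50.0) * (150.0 * 50.0) / (150.0 - 50.0)
    peak = w(t_peak)
    return DriveWaveform(amp_slow=1.0 / peak, amp_fast=1.0 / peak,
                         tau_slow=150.0, tau_fast=50.0)


def generate_surrogate_dataset(n_ranks: int = 125, n_bins: int = 44,
                               dt: float = 5.0,
                               truth_f_R=None, truth_f_F=None,
                               transfer: TransferFunction | None = None,
                               waveform: DriveWaveform | None = None,
                               amplitudes=None,
                               k: float = 1.8, tau_adapt: float = 200.0,
                               w_R: float = 0.0,
                               noise_sd: float = 0.1,
                               seed: int = 0) -> SurrogateDataset:
    """Forward-simulate a novel/familiar rank x time pair.

    The discrete update (tau_R = dt) is stepped from the zero baseline:

        novel:    r_i(t+dt) = Phi( w_R rbar(t) - k a_i(t) + I_i(t) )
        familiar: r_i(t+dt) = Phi( w_R rbar(t) + f_R,i r_max(t)
                                   - k a_i(t) + I_i(t) + f_F,i I_max(t) )

    with a_i the Euler low-pass of r_i and one-hot pre-dependence on
    the top rank (the overlap drive is the top-rank familiar trace
    itself; it enters at the previous bin, so the joint update over
    ranks is explicit). Observation noise is added last to both
    matrices. Identical seeds give bitwise-identical datasets.
    """
    transfer = transfer or TransferFunction.linear()
    waveform = waveform or _default_waveform()
    f_R = (default_truth_f_R(n_ranks) if truth_f_R is None
           else np.asarray(truth_f_R, dtype=float))
    f_F = (default_truth_f_F(n_ranks) if truth_f_F is None
           else np.asarray(truth_f_F, dtype=float))
    if f_R.shape != (n_ranks,) or f_F.shape != (n_ranks,):
        raise ValueError("truth vectors must have length n_ranks")
    if amplitudes is None:
        # rank amplitudes at Gaussian quantiles: inputs ~ N(2, 1.5^2)
        amplitudes = 2.0 + 1.5 * stats.norm.ppf(
            (np.arange(1, n_ranks + 1) - 0.5) / n_ranks)
    amplitudes = np.asarray(amplitudes, dtype=float)

    times = np.arange(n_bins) * dt
    inputs = amplitudes[:, None] * waveform(times)[None, :]

    c = dt / tau_adapt

    def forward(plastic: bool) -> np.ndarray:
        r = np.zeros((n_ranks, n_bins))
        a = np.zeros(n_ranks)
        for t in range(n_bins - 1):
            total = w_R * r[:, t].mean() - k * a + inputs[:, t]
            if plastic:
                total = total + f_R * r[-1, t] + f_F * inputs[-1, t]
            r[:, t + 1] = transfer(total)
            a = a + c * (r[:, t] - a)
        return r

    novel = forward(plastic=False)
    familiar = forward(plastic=True)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        novel = novel + rng.normal(0.0, noise_sd, novel.shape)
        familiar = familiar + rng.normal(0.0, noise_sd, familiar.shape)

    return SurrogateDataset(
        novel=RankTimeMatrix(values=novel, dt=dt, onset_index=0),
        familiar=RankTimeMatrix(values=familiar, dt=dt, onset_index=0),
        truth_f_R=f_R, truth_f_F=f_F, inputs=inputs,
        transfer=transfer, noise_sd=float(noise_sd), seed=int(seed))
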