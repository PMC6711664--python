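"""Shared fixtures: presets, surrogate datasets, and synthetic
top-rank traces for the short-term-depression fit."""

import numpy as np
import pytest

import famdyn as fd
from famdyn.inference import _std_trace_on_data_grid


@pytest.fixture(scope="session")
def fig5_params():
    return fd.presets.fig5_meanfield_params()


@pytest.fixture(scope="session")
def noise_free_surrogate():
    return fd.generate_surrogate_dataset(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_surrogate():
    return fd.generate_surrogate_dataset(noise_sd=0.1, seed=12)


@pytest.fixture(scope="session")
def std_reference_traces():
    """Synthetic stand-in for the passive-viewing top-rank traces.

    The novel max trace is produced by the discrete update from a
    peak-6 difference-of-exponentials drive; the familiar max trace is
    the reduced STD model's response to the input read off the novel
    trace, with ground-truth strengths fg = 2.56, gamma = 0.125.
    """
    n_bins, dt = 44, 5.0
    t = np.arange(n_bins) * dt
    wave = fd.DriveWaveform(amp_slow=1.0, amp_fast=1.0,
                            tau_slow=150.0, tau_fast=50.0)
    t_peak = np.log(3.0) * 75.0
    drive = 6.0 / wave(t_peak) * wave(t)
    r_nov = np.zeros(n_bins)
    r_nov[1:] = drive[:-1]          # tau_R = dt, weak pre-learning recurrence
    truth_fg, truth_gamma = 2.56, 0.125
    r_fam = _std_trace_on_data_grid(truth_fg, truth_gamma, r_nov[1:],
                                    r_nov[0], 5.0, 200.0, dt)
    return {"novel": r_nov, "familiar": r_fam, "dt": dt,
            "truth_fg": truth_fg, "truth_gamma": truth_gamma}


def count_local_maxima(y, after_index=0, tol=0.0):
    """Number of strict local maxima of y[after_index:]."""
    s = np.asarray(y)[after_index:]
    return int(np.sum((s[1:-1] > s[:-2] + tol) & (s[1:-1] > s[2:] + tol)))


def has_rebound(y):
    """True if the trace has a local maximum after its global peak."""
    return count_local_maxima(y, after_index=int(np.argmax(y))) > 0
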