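"""External drive waveforms and stimulus schedules.

The external input to the network is modeled as a constant baseline
plus a time-varying waveform that is the difference of two
exponentials,

    w(t) = a exp(-t/tau_slow) - b exp(-t/tau_fast) + offset,   t >= onset

(zero before onset; the clock t is measured from the waveform onset).
The convention used when fitting population responses sets
offset = b - a so that w(0) = 0.

Successive stimulus presentation is expressed as a schedule in which
each stimulus's waveform restarts at its onset while the preceding
drive decays, either linearly over a fixed interval or exponentially
with a given time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DriveWaveform", "StimulusDrive", "DriveSchedule", "successive_protocol"]


@dataclass(frozen=True)
class DriveWaveform:
    """Difference-of-exponentials drive.

    Parameters
    ----------
    amp_slow, amp_fast
        Amplitudes a and b of the slow and fast exponentials (rate units).
    tau_slow, tau_fast
        Time constants in ms; both must be positive.
    offset
        Additive constant; the population-fit convention is b - a.
    onset
        Time (ms) at which the waveform turns on; value is 0 before.
    """

    amp_slow: float
    amp_fast: float
    tau_slow: float
    tau_fast: float
    offset: float = 0.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_slow <= 0 or self.tau_fast <= 0:
            raise ValueError("drive time constants must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        rel = t - self.onset
        active = rel >= 0
        rel = np.where(active, rel, 0.0)
        val = (self.amp_slow * np.exp(-rel / self.tau_slow)
               - self.amp_fast * np.exp(-rel / self.tau_fast)
               + self.offset)
        out = np.where(active, val, 0.0)
        return out if out.ndim else float(out)

    @classmethod
    def from_fit_convention(cls, a: float, b: float, tau_slow: float,
                              tau_fast: float, onset: float = 0.0) -> "DriveWaveform":
        """Waveform a e^{-t/tau_slow} - b e^{-t/tau_fast} + (b - a)."""
        return cls(amp_slow=a, amp_fast=b, tau_slow=tau_slow,
                   tau_fast=tau_fast, offset=b - a, onset=onset)


def evaluate_drive(waveform: DriveWaveform, t):
    """Evaluate a drive waveform at time(s) ``t`` (ms)."""
    return waveform(t)


@dataclass(frozen=True)
class StimulusDrive:
    """Per-unit external input I_i(t) = baseline + gain * xi_i * w(t).

    ``selectivity`` is the per-unit amplitude vector xi; ``feedforward_gain``
    is the learned uniform scaling gamma of the time-varying input
    (1 before learning).
    """

    baseline: float
    selectivity: np.ndarray
    waveform: DriveWaveform
    feedforward_gain: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "selectivity",
                           np.asarray(self.selectivity, dtype=float))

    @property
    def n_units(self) -> int:
        return self.selectivity.size

    def __call__(self, t: float) -> np.ndarray:
        return self.baseline + self.feedforward_gain * self.selectivity * self.waveform(t)


@dataclass(frozen=True)
class DriveSchedule:
    """Piecewise drive for successive stimulus presentation.

    Each stimulus k has an onset; its waveform runs on its own clock
    from that onset. When the next stimulus arrives, the previous
    stimulus's drive is multiplied by a decay envelope: linear to zero
    over ``decay_ms`` ("linear") or exp(-s/decay_ms) ("exponential"),
    where s is time since the switch.
    """

    waveform: DriveWaveform
    onsets: tuple
    decay: str = "exponential"
    decay_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")
        if self.decay_ms <= 0:
            raise ValueError("decay_ms must be positive")

    def component(self, k: int, t) -> np.ndarray:
        """Drive contributed by stimulus k at time(s) t, including its
        decay after the next stimulus onset."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        onset = self.onsets[k]
        val = self.waveform(t - onset + self.waveform.onset)
        if k + 1 < len(self.onsets):
            switch = self.onsets[k + 1]
            s = t - switch
            after = s > 0
            if self.decay == "linear":
                env = np.clip(1.0 - s / self.decay_ms, 0.0, 1.0)
            else:
                env = np.exp(-np.where(after, s, 0.0) / self.decay_ms)
            val = np.where(after, val * env, val)
        return val

    def __call__(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        total = np.zeros_like(t)
        for k in range(len(self.onsets)):
            total += self.component(k, t)
        return total if total.size > 1 else float(total[0])


def successive_protocol(base_drive: DriveWaveform, n_stimuli: int,
                        present_ms: float, decay: str = "exponential",
                        decay_ms: float = 50.0,
                        first_onset: float = 0.0) -> DriveSchedule:
    """Build a successive-presentation schedule.

    Stimulus k starts at ``first_onset + k * present_ms``; when a new
    stimulus arrives the previous drive decays by the chosen law
    (linearly over ``decay_ms``, or exponentially with time constant
    ``decay_ms``).
    """
    if present_ms <= 0:
        raise ValueError("present_ms must be positive")
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    onsets = tuple(first_onset + k * present_ms for k in range(n_stimuli))
    return DriveSchedule(waveform=base_drive, onsets=onsets,
                         decay=decay, decay_ms=decay_ms)
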