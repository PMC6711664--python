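"""Reduced (mean-field) descriptions of the learned network.

With a linear transfer and uniform pre-learning connectivity, the
N-unit network reduces to four population variables: the mean rate
r_bar and its adaptation a_bar, plus the overlap m = <g_R(xi) r> with
the learned pattern and its adaptation partner n. After learning the
dynamics are

    tau_R dr_bar/dt = -r_bar + w_R r_bar + f_bar_R m - k a_bar
                      + I_bar(t) + f_bar_F I_F(t)
    tau_A da_bar/dt = -a_bar + r_bar
    tau_R dm/dt     = -m + fg_bar_R m - k n + I_M(t) + fg_bar_F I_F(t)
    tau_A dn/dt     = -n + m

Before learning all plasticity coefficients vanish, m = n = 0, and the
system is the 2-variable (r_bar, a_bar) leaky integrator with
adaptation. The (m, n) block is where familiarity changes the regime:
strong potentiation fg_bar_R against slow adaptation turns its impulse
response from monotone decay into a damped oscillation.

Two alternative negative-feedback variants are provided: global
inhibition (shared slow feedback; the m equation loses its private n
and cannot oscillate) and a reduced short-term-depression model for
the high-rate population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transfer import TransferFunction
from .network import SimulationUnstableError

__all__ = [
    "MeanFieldParams",
    "MeanFieldTrajectory",
    "GlobalInhibitionParams",
    "CompetitionParams",
    "CompetitionTrajectory",
    "simulate_meanfield",
    "simulate_global_inhibition",
    "simulate_std_reduced",
    "simulate_competition",
]


def _as_scalar_drive(drive, dt: float):
    """Normalize a drive spec (callable, scalar, or sampled array on the
    dt grid) to a callable (t, step) -> float."""
    if drive is None:
        return lambda t, step: 0.0
    if callable(drive):
        return lambda t, step: float(drive(t))
    arr = np.asarray(drive, dtype=float)
    if arr.ndim == 0:
        c = float(arr)
        return lambda t, step: c
    return lambda t, step: float(arr[min(step, arr.size - 1)])


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the 4-variable reduced dynamics.

    Drives may be DriveWaveform instances, plain callables of time,
    constants, or arrays sampled on the integration grid.
    """

    recurrent_scale: float = 0.0        # w_R
    adapt_strength: float = 1.8         # k
    tau_rate: float = 5.0               # tau_R, ms
    tau_adapt: float = 200.0            # tau_A, ms
    fgbar_R: float = 0.0
    fbar_R: float = 0.0
    fbar_F: float = 0.0
    fgbar_F: float = 0.0
    drive_mean: object = 0.0            # I_bar(t)
    drive_m: object = 0.0               # I_M(t)
    drive_f: object = 0.0               # I_F(t)
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_rate <= 0 or self.tau_adapt <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0 or self.dt > self.tau_rate:
            raise ValueError("need 0 < dt <= tau_rate")


@dataclass(frozen=True)
class MeanFieldTrajectory:
    times: np.ndarray
    rbar: np.ndarray
    abar: np.ndarray
    m: np.ndarray
    n: np.ndarray


def _check_finite(values, step, t) -> None:
    if not np.all(np.isfinite(values)):
        raise SimulationUnstableError(
            f"non-finite mean-field state at step {step} (t = {t:g} ms)")


def simulate_meanfield(params: MeanFieldParams, duration: float,
                       learned: bool = True) -> MeanFieldTrajectory:
    """Euler-integrate the reduced dynamics from the zero baseline.

    With ``learned=False`` the plasticity coefficients are zeroed and
    the (m, n) block stays identically zero, recovering the
    pre-learning 2-variable dynamics.
    """
    dt = params.dt
    if duration < dt:
        raise ValueError("duration must be at least one time step")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    I_mean = _as_scalar_drive(params.drive_mean, dt)
    I_m = _as_scalar_drive(params.drive_m, dt)
    I_f = _as_scalar_drive(params.drive_f, dt)

    if learned:
        fgR, fbR, fbF, fgF = (params.fgbar_R, params.fbar_R,
                              params.fbar_F, params.fgbar_F)
    else:
        fgR = fbR = fbF = fgF = 0.0

    w = params.recurrent_scale
    k = params.adapt_strength
    dt_r = dt / params.tau_rate
    dt_a = dt / params.tau_adapt

    rbar = np.zeros(n_steps + 1)
    abar = np.zeros(n_steps + 1)
    m = np.zeros(n_steps + 1)
    n = np.zeros(n_steps + 1)

    r_, a_, m_, n_ = 0.0, 0.0, 0.0, 0.0
    for step in range(n_steps):
        t = times[step]
        If = I_f(t, step)
        dr = -r_ + w * r_ + fbR * m_ - k * a_ + I_mean(t, step) + fbF * If
        da = -a_ + r_
        if learned:
            dm = -m_ + fgR * m_ - k * n_ + I_m(t, step) + fgF * If
            dn = -n_ + m_
        else:
            dm = dn = 0.0
        r_ += dt_r * dr
        a_ += dt_a * da
        m_ += dt_r * dm
        n_ += dt_a * dn
        _check_finite((r_, a_, m_, n_), step + 1, times[step + 1])
        rbar[step + 1] = r_
        abar[step + 1] = a_
        m[step + 1] = m_
        n[step + 1] = n_

    return MeanFieldTrajectory(times=times, rbar=rbar, abar=abar, m=m, n=n)


@dataclass(frozen=True)
class GlobalInhibitionParams(MeanFieldParams):
    """Shared slow inhibition a^I driven by the mean rate (strength
    k^I = ``adapt_strength``); the m equation has no private feedback."""


def simulate_global_inhibition(params: GlobalInhibitionParams,
                               duration: float) -> MeanFieldTrajectory:
    """3-variable global-inhibition dynamics (r_bar, a^I, m).

    m obeys a first-order equation with no negative-feedback partner,
    so its response to any monotone drive has no overshoot; the n
    channel of the returned trajectory is identically zero.
    """
    dt = params.dt
    if duration < dt:
        raise ValueError("duration must be at least one time step")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    I_mean = _as_scalar_drive(params.drive_mean, dt)
    I_m = _as_scalar_drive(params.drive_m, dt)
    I_f = _as_scalar_drive(params.drive_f, dt)

    w, kI = params.recurrent_scale, params.adapt_strength
    dt_r = dt / params.tau_rate
    dt_a = dt / params.tau_adapt

    rbar = np.zeros(n_steps + 1)
    aI = np.zeros(n_steps + 1)
    m = np.zeros(n_steps + 1)

    r_, a_, m_ = 0.0, 0.0, 0.0
    for step in range(n_steps):
        t = times[step]
        If = I_f(t, step)
        dr = (-r_ + w * r_ + params.fbar_R * m_ - kI * a_
              + I_mean(t, step) + params.fbar_F * If)
        da = -a_ + r_
        dm = -m_ + params.fgbar_R * m_ + I_m(t, step) + params.fgbar_F * If
        r_ += dt_r * dr
        a_ += dt_a * da
        m_ += dt_r * dm
        _check_finite((r_, a_, m_), step + 1, times[step + 1])
        rbar[step + 1] = r_
        aI[step + 1] = a_
        m[step + 1] = m_

    return MeanFieldTrajectory(times=times, rbar=rbar, abar=aI, m=m,
                               n=np.zeros(n_steps + 1))


def simulate_std_reduced(fg_strength: float,
                         depletion_strength: float,
                         tau_recover: float,
                         drive,
                         duration: float,
                         tau_rate: float = 5.0,
                         dt: float = 0.5,
                         baseline_rate: float = 0.0):
    """Reduced short-term-depression model of the high-rate population:

        tau_r dr/dt = -r + fg x r + I_m(t)
        dx/dt = (1 - x)/tau_x - gamma x r

    Resources start at the steady state for ``baseline_rate``. Returns
    (times, rate trace, resource trace).
    """
    if tau_recover <= 0 or tau_rate <= 0 or dt <= 0:
        raise ValueError("time constants and dt must be positive")
    if depletion_strength < 0 or fg_strength < 0:
        raise ValueError("fg_strength and depletion_strength must be >= 0")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    I = _as_scalar_drive(drive, dt)

    r_ = float(baseline_rate)
    x_ = 1.0 / (1.0 + depletion_strength * tau_recover * max(r_, 0.0))
    rate = np.zeros(n_steps + 1)
    res = np.zeros(n_steps + 1)
    rate[0], res[0] = r_, x_

    dt_r = dt / tau_rate
    for step in range(n_steps):
        t = times[step]
        r_new = r_ + dt_r * (-r_ + fg_strength * x_ * r_ + I(t, step))
        x_ += dt * ((1.0 - x_) / tau_recover - depletion_strength * x_ * r_)
        r_ = r_new
        _check_finite((r_, x_), step + 1, times[step + 1])
        rate[step + 1] = r_
        res[step + 1] = x_

    return times, rate, res


@dataclass(frozen=True)
class CompetitionParams:
    """Two mutually inhibitory populations, each following the learned
    m-dynamics for its own stimulus, coupled by -w_c m_j through a
    shifted-rectified transfer (population 2 is held silent until its
    stimulus arrives)."""

    mutual_inhibition: float = 0.1      # w_c
    fgbar_R: float = 0.9
    adapt_strength: float = 1.8
    tau_rate: float = 5.0
    tau_adapt: float = 200.0
    transfer: TransferFunction = field(
        default_factory=lambda: TransferFunction.shifted_rectified(-3.0))
    dt: float = 0.5


@dataclass(frozen=True)
class CompetitionTrajectory:
    times: np.ndarray
    m: np.ndarray   # (2, n_times)
    n: np.ndarray   # (2, n_times)
    onsets: tuple


def simulate_competition(params: CompetitionParams,
                         drives: tuple,
                         onsets: tuple = (0.0, 500.0),
                         duration: float = 2000.0) -> CompetitionTrajectory:
    """Coupled integration of the two-population competition model.

    ``drives`` are per-population waveforms (callables of the time since
    that population's onset). Each population's state is frozen at zero
    before its own onset and released at it.
    """
    if len(onsets) != 2 or len(drives) != 2:
        raise ValueError("exactly two populations")
    dt = params.dt
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt

    phi = params.transfer
    k = params.adapt_strength
    fg = params.fgbar_R
    wc = params.mutual_inhibition
    dt_r = dt / params.tau_rate
    dt_a = dt / params.tau_adapt

    m = np.zeros((2, n_steps + 1))
    n = np.zeros((2, n_steps + 1))
    m_, n_ = np.zeros(2), np.zeros(2)

    for step in range(n_steps):
        t = times[step]
        active = np.array([t >= onsets[0], t >= onsets[1]])
        drive_now = np.array([
            float(drives[i](t - onsets[i])) if active[i] else 0.0
            for i in (0, 1)
        ])
        total = fg * m_ - k * n_ - wc * m_[::-1] + drive_now
        m_new = m_ + dt_r * (-m_ + phi(total))
        n_new = n_ + dt_a * (-n_ + m_)
        m_ = np.where(active, m_new, 0.0)
        n_ = np.where(active, n_new, 0.0)
        _check_finite(m_, step + 1, times[step + 1])
        m[:, step + 1] = m_
        n[:, step + 1] = n_

    return CompetitionTrajectory(times=times, m=m, n=n, onsets=tuple(onsets))
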