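"""Closed-form regime analysis of the 2-variable linear blocks.

Both the pre-learning (r_bar, a_bar) dynamics and the learned (m, n)
block are linear 2-D systems

    tau_R dy1/dt = (-1 + w) y1 - k y2 + I(t)
    tau_A dy2/dt = -y2 + y1

with system matrix A = [[(-1+w)/tau_R, -k/tau_R], [1/tau_A, -1/tau_A]],
where w stands for w_R before learning or fg_bar_R after. Eigenvalues
are (trace +- sqrt(disc))/2 with

    disc = ((-1+w)/tau_R + 1/tau_A)^2 - 4 k / (tau_R tau_A).

disc < 0 gives a damped oscillation (stable focus) with period
2 pi / Im(lambda); the separatrix disc = 0 is a parabola in (w, k).
Stability requires w < 1 + tau_R/tau_A and w - k - 1 < 0.

The two-pulse analysis quantifies the pre-learning constraint that the
response to the second of two successive novel stimuli peaks below the
first, using a piecewise-linear caricature of the rise/decay phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegimeReport",
    "TwoPulseSpec",
    "system_matrix",
    "eigenvalues_2d",
    "discriminant_2d",
    "classify_regime",
    "separatrix_k",
    "second_peak_condition",
]


@dataclass(frozen=True)
class RegimeReport:
    """Eigenvalues, discriminant and qualitative label of a 2-D block.

    ``period`` (ms) is present iff the eigenvalues are complex.
    Boundary cases (disc = 0, marginal stability) are labeled by the
    closed-set convention (node / stable); callers can apply their own
    tolerance using the reported discriminant and eigenvalues.
    """

    eigenvalues: tuple
    discriminant: float
    label: str               # stable_node | stable_focus | unstable
    period: float | None


def system_matrix(feedback: float, k: float, tau_rate: float,
                  tau_adapt: float) -> np.ndarray:
    return np.array([[(-1.0 + feedback) / tau_rate, -k / tau_rate],
                     [1.0 / tau_adapt, -1.0 / tau_adapt]])


def discriminant_2d(feedback: float, k: float, tau_rate: float,
                    tau_adapt: float) -> float:
    """disc = ((-1+w)/tau_R + 1/tau_A)^2 - 4k/(tau_R tau_A), in 1/ms^2."""
    return ((-1.0 + feedback) / tau_rate + 1.0 / tau_adapt) ** 2 \
        - 4.0 * k / (tau_rate * tau_adapt)


def eigenvalues_2d(feedback: float, k: float, tau_rate: float,
                   tau_adapt: float) -> tuple:
    """Complex eigenvalue pair (1/ms) via (trace +- sqrt(disc))/2."""
    if tau_rate <= 0 or tau_adapt <= 0:
        raise ValueError("time constants must be positive")
    trace = (-1.0 + feedback) / tau_rate - 1.0 / tau_adapt
    disc = discriminant_2d(feedback, k, tau_rate, tau_adapt)
    root = complex(math.sqrt(disc)) if disc >= 0 else complex(0.0, math.sqrt(-disc))
    lam1 = (trace + root) / 2.0
    lam2 = (trace - root) / 2.0
    return lam1, lam2


def classify_regime(feedback: float, k: float, tau_rate: float,
                    tau_adapt: float) -> RegimeReport:
    """Label the 2-D block and compute the damped-oscillation period.

    stable_focus: disc < 0 and negative real parts; period 2 pi/Im.
    stable_node: disc >= 0 and stable (boundary disc = 0 included).
    unstable: feedback >= 1 + tau_R/tau_A or feedback - k - 1 >= 0.
    """
    lam1, lam2 = eigenvalues_2d(feedback, k, tau_rate, tau_adapt)
    disc = discriminant_2d(feedback, k, tau_rate, tau_adapt)
    unstable = (feedback >= 1.0 + tau_rate / tau_adapt
                or feedback - k - 1.0 >= 0.0
                or max(lam1.real, lam2.real) > 0.0)
    if unstable:
        label = "unstable"
    elif disc < 0.0:
        label = "stable_focus"
    else:
        label = "stable_node"
    period = 2.0 * math.pi / abs(lam1.imag) if disc < 0.0 else None
    return RegimeReport(eigenvalues=(lam1, lam2), discriminant=disc,
                        label=label, period=period)


def separatrix_k(feedback, tau_rate: float, tau_adapt: float):
    """Adaptation strength on the separatrix disc = 0:
    k = tau_R tau_A / 4 * ((-1+w)/tau_R + 1/tau_A)^2."""
    w = np.asarray(feedback, dtype=float)
    return tau_rate * tau_adapt / 4.0 * ((-1.0 + w) / tau_rate + 1.0 / tau_adapt) ** 2


@dataclass(frozen=True)
class TwoPulseSpec:
    """Piecewise-linear caricature of two successive presentations.

    The response rises linearly to r_0 over t_0 under constant input
    I_0 (with adaptation and input held fixed during the rise), then
    decays linearly to r_1 over t_1. tau_eff = tau_R / (1 - w_R)
    relates the rise slope to the input: r_0 = I_0 t_0 / tau_eff.
    """

    rise_rate_end: float     # r_0
    decay_rate_end: float    # r_1
    rise_duration: float     # t_0, ms
    decay_duration: float    # t_1, ms


def second_peak_condition(spec: TwoPulseSpec, w_R: float, k: float,
                          tau_rate: float, tau_adapt: float) -> dict:
    """Analytic second-peak test for successive novel presentations.

    Integrating the adaptation a over the linear decay from r_0 to r_1
    (a = 0 at the start of the decay) gives

        a_1 = r_0 (1 - e^{-t_1/tau_A})
              + (r_1 - r_0) {1 - (tau_A/t_1)(1 - e^{-t_1/tau_A})}

    The second rise starts from r_1 with effective input I_0 - a_1 k,
    so its peak is (I_0 - a_1 k) t_0 / tau_eff + r_1 with
    I_0 = r_0 tau_eff / t_0. Returns a1, second_peak, tau_eff, and the
    flag second_peak < r_0.
    """
    if spec.rise_duration <= 0 or spec.decay_duration <= 0:
        raise ValueError("pulse durations must be positive")
    if w_R >= 1:
        raise ValueError("requires w_R < 1 (positive tau_eff)")
    r0, r1 = spec.rise_rate_end, spec.decay_rate_end
    t0, t1 = spec.rise_duration, spec.decay_duration
    tau_eff = tau_rate / (1.0 - w_R)
    ea = math.exp(-t1 / tau_adapt)
    a1 = r0 * (1.0 - ea) + (r1 - r0) * (1.0 - (tau_adapt / t1) * (1.0 - ea))
    I0 = r0 * tau_eff / t0
    second_peak = (I0 - a1 * k) * t0 / tau_eff + r1
    return {
        "a1": a1,
        "drive_level": I0,
        "tau_eff": tau_eff,
        "second_peak": second_peak,
        "satisfied": second_peak < r0,
    }
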