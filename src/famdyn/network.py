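"""Full rate-network simulation with firing-rate adaptation.

The network obeys

    tau_r dr_i/dt = -r_i + Phi( sum_j W_ij r_j - k a_i + I_i(t) )
    tau_a da_i/dt = -a_i + r_i

where Phi is a static transfer function, a_i is a low-pass filtered
copy of the rate (spike-frequency adaptation, strength k), and I_i(t)
is the external (feedforward) drive. Integration is explicit Euler on
a uniform grid; with the linear transfer the model is a linear system
whose fixed point under constant input I is r* = I / (1 - w_R + k).

A short-term-depression variant replaces adaptation by a depletable
presynaptic resource x_j in (0, 1]:

    tau_r dr_i/dt = -r_i + sum_j W_ij x_j r_j + I_i(t)
    dx_j/dt = (1 - x_j)/tau_x - gamma x_j r_j
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transfer import TransferFunction

__all__ = [
    "NetworkParams",
    "NetworkTrajectory",
    "STDState",
    "simulate_network",
    "simulate_std_network",
    "uniform_recurrent_weights",
]


class SimulationUnstableError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class NetworkParams:
    """Network-level constants.

    tau_rate and tau_adapt are in ms; adapt_strength is the
    dimensionless adaptation gain k; recurrent_scale w_R sets the
    uniform pre-learning connectivity W_ij = w_R / N.
    """

    n_units: int
    tau_rate: float = 5.0
    tau_adapt: float = 200.0
    adapt_strength: float = 1.8
    recurrent_scale: float = 0.0
    dt: float = 0.5
    adaptation_enabled: bool = True
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.tau_rate <= 0 or self.tau_adapt <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau_rate:
            raise ValueError("dt must not exceed tau_rate (explicit Euler)")


@dataclass(frozen=True)
class NetworkTrajectory:
    """Per-unit rates and adaptation on a uniform time grid (ms)."""

    times: np.ndarray
    rates: np.ndarray       # (n_units, n_times)
    adaptation: np.ndarray  # (n_units, n_times); all-zero if disabled

    def mean_rate(self) -> np.ndarray:
        return self.rates.mean(axis=0)

    def overlap(self, pre_dependence: np.ndarray, normalize: bool = True) -> np.ndarray:
        """g-weighted population average m(t) = (1/N) sum_i g_i r_i(t)."""
        g = np.asarray(pre_dependence, dtype=float)
        m = g @ self.rates
        return m / self.rates.shape[0] if normalize else m

    def to_frame(self):
        """Long-format DataFrame (time_ms, unit, rate, adaptation)."""
        import pandas as pd

        n, t = self.rates.shape
        return pd.DataFrame({
            "time_ms": np.repeat(self.times, n),
            "unit": np.tile(np.arange(n), t),
            "rate": self.rates.T.ravel(),
            "adaptation": self.adaptation.T.ravel(),
        })


@dataclass(frozen=True)
class STDState:
    """Short-term depression parameters and resource initialization.

    depletion_strength is the gamma of the resource equation (per-rate
    units) — distinct from the feedforward scaling gamma of
    StimulusDrive.
    """

    tau_recover: float = 200.0
    depletion_strength: float = 0.125

    def __post_init__(self) -> None:
        if self.tau_recover <= 0:
            raise ValueError("tau_recover must be positive")
        if self.depletion_strength < 0:
            raise ValueError("depletion_strength must be >= 0")

    def steady_resources(self, rates: np.ndarray) -> np.ndarray:
        """x* = 1 / (1 + gamma tau_x r) for a clamped nonnegative rate."""
        r = np.asarray(rates, dtype=float)
        return 1.0 / (1.0 + self.depletion_strength * self.tau_recover * r)


def uniform_recurrent_weights(n_units: int, recurrent_scale: float) -> np.ndarray:
    """Pre-learning connectivity W_ij = w_R / N."""
    return np.full((n_units, n_units), recurrent_scale / n_units)


def _resolve_drive(drive, n_units: int):
    """Accept a StimulusDrive, a callable t -> vector/scalar, a constant
    scalar, or a constant vector."""
    if callable(drive):
        def fn(t):
            v = np.asarray(drive(t), dtype=float)
            return np.broadcast_to(v, (n_units,))
        return fn
    const = np.broadcast_to(np.asarray(drive, dtype=float), (n_units,)).copy()
    return lambda t: const


def _check_finite(state: np.ndarray, step: int, t: float) -> None:
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise SimulationUnstableError(
            f"non-finite state at step {step} (t = {t:g} ms), first bad unit {bad}; "
            "the integration is unstable — reduce dt or check parameters")


def simulate_network(params: NetworkParams,
                     recurrent_weights: np.ndarray,
                     drive,
                     transfer: TransferFunction | None = None,
                     duration: float = 500.0,
                     initial_rates=None,
                     initial_adaptation=None) -> NetworkTrajectory:
    """Explicit-Euler trajectory of the adapting rate network.

    ``drive`` may be a StimulusDrive, any callable t -> per-unit input,
    or a constant (scalar or length-N vector). ``initial_rates`` /
    ``initial_adaptation`` default to zero (the declared baseline
    state); pass the constant-input fixed point to start at rest under
    a baseline drive.
    """
    transfer = transfer or TransferFunction.linear()
    n = params.n_units
    W = np.asarray(recurrent_weights, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"recurrent_weights must be {n}x{n}, got {W.shape}")
    if duration < params.dt:
        raise ValueError("duration must be at least one time step")

    drive_fn = _resolve_drive(drive, n)
    n_steps = int(round(duration / params.dt))
    times = np.arange(n_steps + 1) * params.dt

    r = np.zeros(n) if initial_rates is None else np.array(initial_rates, dtype=float)
    a = np.zeros(n) if initial_adaptation is None else np.array(initial_adaptation, dtype=float)

    rates = np.empty((n, n_steps + 1))
    adapt = np.empty((n, n_steps + 1))
    rates[:, 0] = r
    adapt[:, 0] = a

    k = params.adapt_strength if params.adaptation_enabled else 0.0
    dt_r = params.dt / params.tau_rate
    dt_a = params.dt / params.tau_adapt

    for step in range(n_steps):
        t = times[step]
        total_input = W @ r - k * a + drive_fn(t)
        r_new = r + dt_r * (-r + transfer(total_input))
        if params.clip_at_zero:
            np.maximum(r_new, 0.0, out=r_new)
        if params.adaptation_enabled:
            a = a + dt_a * (-a + r)
        r = r_new
        _check_finite(r, step + 1, times[step + 1])
        rates[:, step + 1] = r
        adapt[:, step + 1] = a

    if not params.adaptation_enabled:
        adapt[:] = 0.0
    return NetworkTrajectory(times=times, rates=rates, adaptation=adapt)


def simulate_std_network(params: NetworkParams,
                         recurrent_weights: np.ndarray,
                         std: STDState,
                         drive,
                         duration: float = 500.0,
                         baseline_rate: float = 0.0,
                         initial_rates=None):
    """Co-integrate rates and presynaptic resources.

    The recurrent drive is W_ij x_j r_j; resources start at the steady
    state for ``baseline_rate``. Returns (NetworkTrajectory, resources)
    with resources shaped (n_units, n_times); the trajectory's
    adaptation channel is zero (this model has no adaptation current).
    """
    n = params.n_units
    W = np.asarray(recurrent_weights, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"recurrent_weights must be {n}x{n}, got {W.shape}")

    drive_fn = _resolve_drive(drive, n)
    n_steps = int(round(duration / params.dt))
    times = np.arange(n_steps + 1) * params.dt

    r = (np.full(n, float(baseline_rate)) if initial_rates is None
         else np.array(initial_rates, dtype=float))
    x = std.steady_resources(np.maximum(r, 0.0))

    rates = np.empty((n, n_steps + 1))
    resources = np.empty((n, n_steps + 1))
    rates[:, 0] = r
    resources[:, 0] = x

    dt = params.dt
    dt_r = dt / params.tau_rate

    for step in range(n_steps):
        t = times[step]
        r_new = r + dt_r * (-r + W @ (x * r) + drive_fn(t))
        x = x + dt * ((1.0 - x) / std.tau_recover - std.depletion_strength * x * r)
        r = r_new
        _check_finite(r, step + 1, times[step + 1])
        _check_finite(x, step + 1, times[step + 1])
        rates[:, step + 1] = r
        resources[:, step + 1] = x

    traj = NetworkTrajectory(times=times, rates=rates,
                             adaptation=np.zeros_like(rates))
    return traj, resources
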