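"""Inferring post-synaptic plasticity dependence from rank-ordered
response time courses.

The pipeline mirrors how single-unit recordings from a passive-viewing
experiment are analyzed. Per neuron, responses are z-scored against the
time-averaged activity over novel stimuli in an early window, stimuli
are rank-ordered by time-averaged response within each condition, and
the normalized traces are averaged across neurons at each rank. That
yields one rank x time matrix per condition (novel / familiar): the
lingua franca shared by data, the synthetic generator and the fitters.

Inference exploits the discretization tau_R = dt (5 ms), under which
the rate update collapses to

    r_i(t + dt) = Phi( w_R rbar(t) + f_R,i r_max(t) - k a_i(t)
                       + I_i(t) + f_F,i I_max(t) )

with the plasticity terms absent before learning. The external input
I_i(t) is therefore read off the novel traces exactly
(``reconstruct_input``), and the per-rank post-synaptic dependences
(f_R,i, f_F,i) are the solution of an ordinary weighted least-squares
problem on the familiar traces (``fit_postsynaptic_dependence``),
using the measured top-rank familiar trace as the overlap drive
(teacher forcing) and a one-hot pre-dependence on the top rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .transfer import TransferFunction
from .meanfield import simulate_std_reduced

__all__ = [
    "RankTimeMatrix",
    "InferenceResult",
    "STDFit",
    "normalize_and_rank",
    "rebound_strength",
    "adaptation_trace",
    "reconstruct_input",
    "fit_postsynaptic_dependence",
    "derive_transfer_from_novel",
    "fit_std_params",
]


@dataclass(frozen=True)
class RankTimeMatrix:
    """Normalized responses indexed by stimulus rank x time bin.

    Ranks are sorted ascending by time-averaged activity, so the last
    row is the most preferred (maximum) stimulus. ``dt`` is the bin
    width in ms and ``onset_index`` the bin of stimulus onset (time 0).
    """

    values: np.ndarray
    dt: float = 5.0
    onset_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (rank x time)")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_ranks(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin times in ms relative to stimulus onset."""
        return (np.arange(self.n_bins) - self.onset_index) * self.dt

    def top_rank_trace(self) -> np.ndarray:
        return self.values[-1]

    def time_window_bins(self, window) -> np.ndarray:
        """Indices of bins whose onset-relative time lies in [lo, hi]."""
        lo, hi = window
        t = self.times
        idx = np.flatnonzero((t >= lo) & (t <= hi))
        if idx.size == 0:
            raise ValueError(f"window {window} ms contains no bins "
                             f"(trace spans {t[0]:g}..{t[-1]:g} ms)")
        return idx

    def time_average(self, window) -> np.ndarray:
        return self.values[:, self.time_window_bins(window)].mean(axis=1)


@dataclass(frozen=True)
class InferenceResult:
    """Per-rank post-synaptic dependences and fit diagnostics."""

    f_R: np.ndarray
    f_F: np.ndarray
    residuals: np.ndarray        # per-rank weighted SSE
    weights: np.ndarray          # per-bin fitting weights
    rank_deficient: np.ndarray = field(default=None)  # per-rank flag


@dataclass(frozen=True)
class STDFit:
    """Best-fit strengths of the reduced short-term-depression model."""

    fg_strength: float
    depletion_strength: float
    loss: float


# ----------------------------------------------------------------------
# normalization and ranking
# ----------------------------------------------------------------------

def normalize_and_rank(novel_raw, familiar_raw, dt: float = 5.0,
                       onset_index: int = 0,
                       z_window=(80.0, 200.0),
                       avg_window=None):
    """Z-score per neuron against novel responses and average by rank.

    Parameters
    ----------
    novel_raw, familiar_raw
        Arrays (n_neurons, n_stimuli, n_bins) of firing rates; the two
        conditions may have different stimulus counts but must share
        neurons and the time grid.
    z_window
        Window (ms, onset-relative, inclusive) over which each
        stimulus's response is time-averaged; the mean and standard
        deviation of those averages across *novel* stimuli normalize
        all of that neuron's rates.
    avg_window
        Window used to rank stimuli by time-averaged activity
        (defaults to ``z_window``).

    Returns ``(novel, familiar)`` RankTimeMatrix pairs, averaged across
    neurons at each rank. A neuron whose novel time averages have zero
    variance is rejected (its index is named in the error).
    """
    nov = np.asarray(novel_raw, dtype=float)
    fam = np.asarray(familiar_raw, dtype=float)
    if nov.ndim != 3 or fam.ndim != 3:
        raise ValueError("raw arrays must be 3-D (neuron, stimulus, time)")
    if nov.shape[0] != fam.shape[0] or nov.shape[2] != fam.shape[2]:
        raise ValueError("conditions must share neurons and time grid")
    if nov.shape[1] < 2 or fam.shape[1] < 2:
        raise ValueError("need at least two stimuli per condition")
    avg_window = z_window if avg_window is None else avg_window

    t = (np.arange(nov.shape[2]) - onset_index) * dt
    zbins = np.flatnonzero((t >= z_window[0]) & (t <= z_window[1]))
    abins = np.flatnonzero((t >= avg_window[0]) & (t <= avg_window[1]))
    if zbins.size == 0 or abins.size == 0:
        raise ValueError("normalization/ranking window contains no bins")

    out = {}
    z_nov = np.empty_like(nov)
    z_fam = np.empty_like(fam)
    for i in range(nov.shape[0]):
        s = nov[i][:, zbins].mean(axis=1)      # time-averaged novel activity
        mu, sd = float(s.mean()), float(s.std())
        if sd == 0.0:
            raise ValueError(f"neuron {i}: zero variance of time-averaged "
                             "novel activity; cannot z-score")
        z_nov[i] = (nov[i] - mu) / sd
        z_fam[i] = (fam[i] - mu) / sd

    for name, z in (("novel", z_nov), ("familiar", z_fam)):
        n_neurons, n_stim, n_bins = z.shape
        ranked = np.empty((n_neurons, n_stim, n_bins))
        for i in range(n_neurons):
            order = np.argsort(z[i][:, abins].mean(axis=1), kind="stable")
            ranked[i] = z[i][order]
        out[name] = RankTimeMatrix(values=ranked.mean(axis=0), dt=dt,
                                   onset_index=onset_index)
    return out["novel"], out["familiar"]


def rebound_strength(trace, dt: float = 5.0, onset_index: int = 0,
                     window=(230.0, 320.0)) -> float:
    """OLS slope (rate units per ms) of a trace over a late window.

    Quantifies the return phase of the damped oscillation; positive at
    ranks whose recurrent inputs were potentiated.
    """
    trace = np.asarray(trace, dtype=float)
    t = (np.arange(trace.size) - onset_index) * dt
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any() or t[-1] < window[1] or t[0] > window[0]:
        raise ValueError(f"window {window} ms not contained in trace "
                         f"({t[0]:g}..{t[-1]:g} ms)")
    x, y = t[sel], trace[sel]
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


# ----------------------------------------------------------------------
# input reconstruction and plasticity fitting
# ----------------------------------------------------------------------

def adaptation_trace(rates: np.ndarray, dt: float, tau_adapt: float) -> np.ndarray:
    """Euler low-pass of rates along the last axis, a(0) = r(0)."""
    r = np.asarray(rates, dtype=float)
    a = np.empty_like(r)
    a[..., 0] = r[..., 0]
    c = dt / tau_adapt
    for t in range(r.shape[-1] - 1):
        a[..., t + 1] = a[..., t] + c * (r[..., t] - a[..., t])
    return a


def reconstruct_input(novel: RankTimeMatrix,
                      transfer: TransferFunction | None = None,
                      k: float = 1.8, tau_adapt: float = 200.0,
                      w_R: float = 0.0) -> np.ndarray:
    """External input per rank from the novel traces.

    With tau_R = dt the discrete update inverts exactly:

        I_i(t) = Phi^{-1}(r_i(t+dt)) - w_R rbar(t) + k a_i(t)

    Returns an (n_ranks, n_bins - 1) array defined on bins 0..T-2.
    """
    transfer = transfer or TransferFunction.linear()
    if not transfer.invertible:
        raise ValueError("transfer function is not invertible")
    r = novel.values
    a = adaptation_trace(r, novel.dt, tau_adapt)
    rbar = r.mean(axis=0)
    return (transfer.inverse(r[:, 1:]) - w_R * rbar[None, :-1]
            + k * a[:, :-1])


def fit_postsynaptic_dependence(novel: RankTimeMatrix,
                                familiar: RankTimeMatrix,
                                transfer: TransferFunction | None = None,
                                k: float = 1.8, tau_adapt: float = 200.0,
                                w_R: float = 0.0,
                                late_weight: float = 5.0,
                                late_onset_ms: float = 230.0) -> InferenceResult:
    """Per-rank weighted least squares for (f_R, f_F).

    The pre-dependence is one-hot on the top rank, so the overlap drive
    is the measured top-rank familiar trace (teacher forcing) and the
    feedforward term uses the reconstructed top-rank input. Each rank
    contributes T-1 equations in its two unknowns; bins at or after
    ``late_onset_ms`` carry weight ``late_weight`` to pin the rebound.
    """
    transfer = transfer or TransferFunction.linear()
    if novel.values.shape != familiar.values.shape:
        raise ValueError("novel and familiar matrices must share shape")
    I = reconstruct_input(novel, transfer, k=k, tau_adapt=tau_adapt, w_R=w_R)
    r_fam = familiar.values
    a_fam = adaptation_trace(r_fam, familiar.dt, tau_adapt)
    rbar_fam = r_fam.mean(axis=0)

    r_max = familiar.top_rank_trace()[:-1]   # drive at bins 0..T-2
    I_max = I[-1]
    t_rhs = familiar.times[:-1]
    w = np.where(t_rhs >= late_onset_ms, late_weight, 1.0)
    sw = np.sqrt(w)

    X = np.column_stack([r_max, I_max])
    n_ranks = familiar.n_ranks
    f_R = np.empty(n_ranks)
    f_F = np.empty(n_ranks)
    sse = np.empty(n_ranks)
    deficient = np.zeros(n_ranks, dtype=bool)

    Xw = X * sw[:, None]
    rank_X = np.linalg.matrix_rank(Xw)
    for i in range(n_ranks):
        y = (transfer.inverse(r_fam[i, 1:]) - w_R * rbar_fam[:-1]
             + k * a_fam[i, :-1] - I[i])
        sol, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
        f_R[i], f_F[i] = sol
        resid = y - X @ sol
        sse[i] = float(w @ resid ** 2)
        deficient[i] = rank_X < 2

    return InferenceResult(f_R=f_R, f_F=f_F, residuals=sse, weights=w,
                           rank_deficient=deficient)


# ----------------------------------------------------------------------
# nonlinear transfer from time-averaged novel responses
# ----------------------------------------------------------------------

def derive_transfer_from_novel(novel_time_avg, window=(75.0, 200.0)) -> TransferFunction:
    """Tabulated monotone transfer by Gaussian quantile matching.

    Assuming the synaptic inputs across stimuli are Gaussian, rank i's
    time-averaged novel response (ranks ascending) is paired with the
    standard-normal quantile at probability (i - 0.5)/n. Any rate-order
    violations are removed by isotonic regression so the returned table
    is monotone. Pass either a per-rank vector of time-averaged rates
    or a RankTimeMatrix (averaged over ``window``).
    """
    if isinstance(novel_time_avg, RankTimeMatrix):
        rates = novel_time_avg.time_average(window)
    else:
        rates = np.asarray(novel_time_avg, dtype=float)
    n = rates.size
    if n < 3:
        raise ValueError("need at least 3 ranks to tabulate a transfer")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    iso = optimize.isotonic_regression(rates).x
    return TransferFunction.tabulated(q, iso)


# ----------------------------------------------------------------------
# short-term-depression fit
# ----------------------------------------------------------------------

def _std_trace_on_data_grid(fg: float, gamma: float, I_m: np.ndarray,
                            r0: float, tau_rate: float, tau_recover: float,
                            dt: float, dt_internal: float = 0.25) -> np.ndarray:
    """Forward-simulate the reduced STD model against binned data.

    The drive is held constant within each data bin (zero-order hold)
    and the ODEs are integrated at a fine internal step — the resource
    equation is stiff at high rates, so stepping at the 5 ms data
    resolution would be unstable — then the rate is sampled at the bin
    edges. Returns len(I_m) + 1 samples aligned with the data bins.
    """
    sub = max(1, int(round(dt / dt_internal)))
    I_m = np.asarray(I_m, dtype=float)
    drive_fine = np.repeat(I_m, sub)
    _, rate, _ = simulate_std_reduced(
        fg_strength=fg, depletion_strength=gamma, tau_recover=tau_recover,
        drive=drive_fine, duration=len(drive_fine) * (dt / sub),
        tau_rate=tau_rate, dt=dt / sub, baseline_rate=r0)
    return rate[::sub]


def fit_std_params(novel_max, familiar_max, dt: float = 5.0,
                   tau_rate: float = 5.0, tau_recover: float = 200.0,
                   fg_bounds=(0.1, 10.0), gamma_bounds=(1e-3, 3.0),
                   grid_size: int = 60) -> STDFit:
    """Two-parameter fit of the reduced STD model to the top-rank traces.

    The drive I_m is read off the novel max trace (with tau_R = dt and
    weak pre-learning recurrence, I_m(t) = r^nov(t + dt)); the familiar
    max trace is then fitted over (fg, gamma) by SSE, minimized on a
    fixed log-spaced grid followed by Nelder-Mead refinement from the
    grid optimum. Deterministic given the grid specification.
    """
    r_nov = np.asarray(novel_max, dtype=float)
    r_fam = np.asarray(familiar_max, dtype=float)
    if r_nov.shape != r_fam.shape or r_nov.ndim != 1:
        raise ValueError("traces must be 1-D and share the time grid")
    I_m = r_nov[1:]
    r0 = float(r_fam[0])

    def loss(fg, gamma):
        if fg < 0 or gamma < 0:
            return np.inf
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                sim = _std_trace_on_data_grid(fg, gamma, I_m, r0, tau_rate,
                                              tau_recover, dt)
        except RuntimeError:
            return np.inf
        if not np.all(np.isfinite(sim)):
            return np.inf
        return float(np.sum((sim - r_fam) ** 2))

    fg_grid = np.geomspace(*fg_bounds, grid_size)
    ga_grid = np.geomspace(*gamma_bounds, grid_size)
    losses = np.array([[loss(fg, ga) for ga in ga_grid] for fg in fg_grid])
    i, j = np.unravel_index(np.argmin(losses), losses.shape)

    res = optimize.minimize(
        lambda p: loss(np.exp(p[0]), np.exp(p[1])),
        x0=np.log([fg_grid[i], ga_grid[j]]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    fg, ga = np.exp(res.x)
    return STDFit(fg_strength=float(fg), depletion_strength=float(ga),
                  loss=float(res.fun))
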