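"""Builders that turn shipped preset files into parameter objects."""

from __future__ import annotations

import numpy as np

from .drives import DriveWaveform, successive_protocol
from .io import load_preset
from .meanfield import CompetitionParams, MeanFieldParams
from .transfer import TransferFunction

__all__ = [
    "fig5_meanfield_params",
    "fig5_successive_params",
    "fig7_competition_setup",
    "fig4_setup",
]


def _waveform(spec: dict, onset: float = 0.0) -> DriveWaveform:
    return DriveWaveform.from_fit_convention(
        a=spec["a"], b=spec["b"], tau_slow=spec["tau_slow"],
        tau_fast=spec["tau_fast"], onset=onset)


def fig5_meanfield_params(dt: float = 0.5) -> MeanFieldParams:
    """4-variable reduced dynamics fitted to dimming-detection data."""
    p = load_preset("fig5")
    mf = p["meanfield"]
    drive_m = _waveform(p["drive_m"])
    drive_f = drive_m if p["drive_f"] == "drive_m" else _waveform(p["drive_f"])
    return MeanFieldParams(
        recurrent_scale=mf["recurrent_scale"],
        adapt_strength=mf["adapt_strength"],
        tau_rate=mf["tau_rate"], tau_adapt=mf["tau_adapt"],
        fgbar_R=mf["fgbar_R"], fbar_R=mf["fbar_R"],
        fbar_F=mf["fbar_F"], fgbar_F=mf["fgbar_F"],
        drive_mean=_waveform(p["drive_mean"]),
        drive_m=drive_m, drive_f=drive_f, dt=dt)


def fig5_successive_params(n_stimuli: int = 2, dt: float = 0.5) -> MeanFieldParams:
    """Same dynamics under successive presentation: each stimulus's
    waveform restarts at its onset, the previous drive decaying
    exponentially (50 ms)."""
    p = load_preset("fig5")
    base = fig5_meanfield_params(dt=dt)
    sp = p["successive"]
    sched_mean = successive_protocol(base.drive_mean, n_stimuli,
                                     sp["present_ms"], sp["decay"],
                                     sp["decay_ms"])
    sched_m = successive_protocol(base.drive_m, n_stimuli,
                                  sp["present_ms"], sp["decay"],
                                  sp["decay_ms"])
    sched_f = successive_protocol(base.drive_f, n_stimuli,
                                  sp["present_ms"], sp["decay"],
                                  sp["decay_ms"])
    return MeanFieldParams(
        recurrent_scale=base.recurrent_scale,
        adapt_strength=base.adapt_strength,
        tau_rate=base.tau_rate, tau_adapt=base.tau_adapt,
        fgbar_R=base.fgbar_R, fbar_R=base.fbar_R,
        fbar_F=base.fbar_F, fgbar_F=base.fgbar_F,
        drive_mean=sched_mean, drive_m=sched_m, drive_f=sched_f, dt=dt)


def fig7_competition_setup(dt: float = 0.5):
    """(CompetitionParams, per-population drives, onsets)."""
    p = load_preset("fig7")
    c = p["competition"]
    params = CompetitionParams(
        mutual_inhibition=c["mutual_inhibition"], fgbar_R=c["fgbar_R"],
        adapt_strength=c["adapt_strength"], tau_rate=c["tau_rate"],
        tau_adapt=c["tau_adapt"],
        transfer=TransferFunction.shifted_rectified(c["transfer_threshold"]),
        dt=dt)
    d = p["drive"]
    wave = DriveWaveform(amp_slow=1.0, amp_fast=1.0,
                         tau_slow=d["tau_slow"], tau_fast=d["tau_fast"])
    return params, (wave, wave), tuple(p["onsets"])


def fig4_setup(seed: int = 0, dt: float = 0.5):
    """Full-network configuration: parameters, gamma-distributed
    selectivity, Hebbian update, and learned feedforward scaling.

    Returns a dict with NetworkParams, the pre-learning weights, the
    selectivity vector, the drive waveform, the baseline input solved
    from the fixed point r* = baseline_rate, and preset scalars.
    """
    from .network import NetworkParams, uniform_recurrent_weights
    from .synthetic import sample_selectivity

    p = load_preset("fig4")
    net = p["network"]
    params = NetworkParams(
        n_units=net["n_units"], tau_rate=net["tau_rate"],
        tau_adapt=net["tau_adapt"], adapt_strength=net["adapt_strength"],
        recurrent_scale=net["recurrent_scale"], dt=dt)
    xi = sample_selectivity(net["n_units"],
                            shape=p["plasticity"]["selectivity_shape"],
                            seed=seed)
    W0 = uniform_recurrent_weights(net["n_units"], net["recurrent_scale"])
    wave = DriveWaveform(amp_slow=1.0, amp_fast=1.0,
                         tau_slow=p["drive"]["tau_slow"],
                         tau_fast=p["drive"]["tau_fast"])
    r_star = p["drive"]["baseline_rate"]
    # fixed point of the linear network under constant input:
    # r* = I_const / (1 - w_R + k)
    i_const = r_star * (1.0 - net["recurrent_scale"] + net["adapt_strength"])
    return {
        "params": params,
        "weights": W0,
        "selectivity": xi,
        "waveform": wave,
        "baseline_input": i_const,
        "baseline_rate": r_star,
        "hebbian_strength": p["plasticity"]["hebbian_strength"],
        "feedforward_gain": p["plasticity"]["feedforward_gain"],
        "protocol": p["protocol"],
    }
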