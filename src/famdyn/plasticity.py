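"""Separable synaptic plasticity rules and their mean-field coefficients.

A one-shot learning event updates the recurrent weights by a separable
(rank-1) rule

    dW_ij = (1/N) f(xi_i) g(xi_j)

where xi_i is unit i's time-averaged activity during the stimulus
before learning, f is the post-synaptic dependence and g the
pre-synaptic dependence. A zero-sum g (sum_j g(xi_j) = 0) preserves
each unit's total incoming weight. Feedforward plasticity uses the
same factorized form, applied in the printed convention without the
1/N factor.

The mean-field reduction of the learned network depends on the rule
only through population averages: f_bar = <f>, fg_bar = <f g_R>, and
the g-weighted input projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeparableRule",
    "MeanFieldCoefficients",
    "separable_delta",
    "hebbian_delta",
    "hebbian_rule",
    "meanfield_coefficients",
    "orthogonalize_selectivity",
]


@dataclass(frozen=True)
class SeparableRule:
    """Tabulated post-dependence f and pre-dependence g of one rule."""

    post_dependence: np.ndarray
    pre_dependence: np.ndarray
    normalize_by_n: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.post_dependence, dtype=float)
        g = np.asarray(self.pre_dependence, dtype=float)
        if f.shape != g.shape or f.ndim != 1:
            raise ValueError("post_dependence and pre_dependence must be "
                             "1-D arrays of equal length")
        object.__setattr__(self, "post_dependence", f)
        object.__setattr__(self, "pre_dependence", g)

    @property
    def n_units(self) -> int:
        return self.post_dependence.size

    def assert_zero_sum(self, tol: float = 1e-12) -> None:
        s = float(self.pre_dependence.sum())
        if abs(s) > tol * max(1.0, float(np.abs(self.pre_dependence).sum())):
            raise ValueError(f"pre-dependence is not zero-sum (sum = {s:g})")


@dataclass(frozen=True)
class MeanFieldCoefficients:
    """Population averages entering the 4-variable reduced dynamics.

    fbar_R/fbar_F are <f_R>/<f_F>; fgbar_R/fgbar_F are <f_R g_R> and
    <f_F g_R>; input_mean, input_m, input_f are the plain, g_R-weighted
    and g_F-weighted averages of the external input.
    """

    fbar_R: float
    fbar_F: float
    fgbar_R: float
    fgbar_F: float
    input_mean: float = 0.0
    input_m: float = 0.0
    input_f: float = 0.0


def separable_delta(rule: SeparableRule) -> np.ndarray:
    """Rank-1 weight update dW_ij = f_i g_j (/N if normalize_by_n)."""
    dW = np.outer(rule.post_dependence, rule.pre_dependence)
    if rule.normalize_by_n:
        dW /= rule.n_units
    return dW


def hebbian_rule(selectivity: np.ndarray, strength: float) -> SeparableRule:
    """Hebbian rule dW_ij = alpha/(N var(xi)) xi_i (xi_j - xi_bar) as a
    separable rule with f = alpha xi / var(xi), g = xi - xi_bar.

    var is the population (1/N) variance, so that the induced
    mean-field coefficient <f g> equals alpha exactly.
    """
    xi = np.asarray(selectivity, dtype=float)
    var = float(np.var(xi))  # population variance
    if var <= 0:
        raise ValueError("selectivity must not be constant (zero variance)")
    f = strength * xi / var
    g = xi - xi.mean()
    return SeparableRule(post_dependence=f, pre_dependence=g, normalize_by_n=True)


def hebbian_delta(selectivity: np.ndarray, strength: float) -> np.ndarray:
    """Weight update of the Hebbian rule; rows sum to zero exactly."""
    return separable_delta(hebbian_rule(selectivity, strength))


def meanfield_coefficients(recurrent: SeparableRule,
                           feedforward: SeparableRule | None = None,
                           external_input: np.ndarray | None = None) -> MeanFieldCoefficients:
    """Reduce separable rules and a per-unit input to the averages the
    4-variable mean-field dynamics needs.

    The overlap direction is the recurrent pre-dependence g_R: fg_bar_k
    = <f_k g_R> for k in {R, F}; the input projections are I_mean =
    <I>, I_M = <g_R I>, I_F = <g_F I>.
    """
    f_R = recurrent.post_dependence
    g_R = recurrent.pre_dependence
    n = f_R.size
    fbar_R = float(f_R.mean())
    fgbar_R = float((f_R * g_R).mean())

    if feedforward is not None:
        if feedforward.n_units != n:
            raise ValueError("rule lengths differ")
        f_F = feedforward.post_dependence
        g_F = feedforward.pre_dependence
        fbar_F = float(f_F.mean())
        fgbar_F = float((f_F * g_R).mean())
    else:
        f_F = g_F = None
        fbar_F = fgbar_F = 0.0

    input_mean = input_m = input_f = 0.0
    if external_input is not None:
        I = np.asarray(external_input, dtype=float)
        if I.shape != (n,):
            raise ValueError("external_input length mismatch")
        input_mean = float(I.mean())
        input_m = float((g_R * I).mean())
        if g_F is not None:
            input_f = float((g_F * I).mean())

    return MeanFieldCoefficients(fbar_R=fbar_R, fbar_F=fbar_F,
                                 fgbar_R=fgbar_R, fgbar_F=fgbar_F,
                                 input_mean=input_mean, input_m=input_m,
                                 input_f=input_f)


def orthogonalize_selectivity(xi1: np.ndarray, xi2: np.ndarray) -> tuple:
    """Decorrelate two selectivity patterns for two-stimulus learning.

    Independent draws are only approximately uncorrelated at finite N.
    This removes the empirical cross-projection between the centered
    patterns (Gram-Schmidt on the fluctuations, means preserved) so
    that sum_j f(xi^1_j) g(xi^2_j) = 0 holds exactly for rules whose f
    is affine in xi and whose g is the centered pattern.
    """
    x1 = np.asarray(xi1, dtype=float).copy()
    x2 = np.asarray(xi2, dtype=float).copy()
    c1 = x1 - x1.mean()
    c2 = x2 - x2.mean()
    denom = float(c1 @ c1)
    if denom == 0:
        raise ValueError("first pattern is constant")
    c2 = c2 - (c1 @ c2) / denom * c1
    return x1, c2 + x2.mean()
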