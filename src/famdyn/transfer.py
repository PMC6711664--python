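"""Static transfer functions (f-I curves).

The network model maps total synaptic input to firing rate through a
static transfer function Phi. Three families are supported:

* ``linear`` — Phi(x) = x, the assumption under which the mean-field
  reduction and the inference pipeline are exact.
* ``shifted_rectified`` — Phi(x) = x for x >= threshold, 0 otherwise.
  With threshold < 0 this admits negative outputs on [threshold, 0);
  it is used literally like that by the two-population competition
  model (threshold -3).
* ``tabulated_monotone`` — a monotone piecewise-linear curve through
  sampled (input, rate) pairs, invertible on the convex hull of its
  rate samples; produced by quantile-matching time-averaged responses
  against Gaussian input statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransferFunction"]


@dataclass(frozen=True)
class TransferFunction:
    """Monotone nondecreasing static f-I curve with optional inverse.

    Parameters
    ----------
    kind
        One of ``linear``, ``shifted_rectified``, ``tabulated_monotone``.
    threshold
        Rectification threshold in input units (shifted_rectified only).
    table_x, table_y
        Paired monotone (input, rate) samples (tabulated only).
    """

    kind: str = "linear"
    threshold: float = 0.0
    table_x: np.ndarray | None = field(default=None)
    table_y: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "shifted_rectified", "tabulated_monotone"):
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.kind == "tabulated_monotone":
            if self.table_x is None or self.table_y is None:
                raise ValueError("tabulated transfer requires table_x and table_y")
            x = np.asarray(self.table_x, dtype=float)
            y = np.asarray(self.table_y, dtype=float)
            if x.ndim != 1 or x.shape != y.shape or x.size < 2:
                raise ValueError("table must be two equal-length 1-D arrays, >= 2 points")
            if np.any(np.diff(x) <= 0):
                raise ValueError("table_x must be strictly increasing")
            if np.any(np.diff(y) < 0):
                raise ValueError("table_y must be nondecreasing")
            object.__setattr__(self, "table_x", x)
            object.__setattr__(self, "table_y", y)

    # ------------------------------------------------------------------
    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return x.copy() if x.ndim else float(x)
        if self.kind == "shifted_rectified":
            out = np.where(x >= self.threshold, x, 0.0)
            return out if x.ndim else float(out)
        # tabulated: piecewise linear with linear extrapolation at the ends
        out = _interp_extrap(x, self.table_x, self.table_y)
        return out if x.ndim else float(out)

    @property
    def invertible(self) -> bool:
        if self.kind == "linear":
            return True
        if self.kind == "tabulated_monotone":
            return bool(np.all(np.diff(self.table_y) > 0))
        return False

    def inverse(self, r):
        """Map rate back to input. Exact for linear; piecewise-linear
        (with linear extrapolation, see notes) for tabulated curves."""
        r = np.asarray(r, dtype=float)
        if self.kind == "linear":
            return r.copy() if r.ndim else float(r)
        if self.kind == "tabulated_monotone":
            if not self.invertible:
                raise ValueError("tabulated transfer has flat segments; not invertible")
            out = _interp_extrap(r, self.table_y, self.table_x)
            return out if r.ndim else float(out)
        raise ValueError(f"transfer kind {self.kind!r} is not invertible")

    @classmethod
    def linear(cls) -> "TransferFunction":
        return cls(kind="linear")

    @classmethod
    def shifted_rectified(cls, threshold: float) -> "TransferFunction":
        return cls(kind="shifted_rectified", threshold=float(threshold))

    @classmethod
    def tabulated(cls, inputs, rates) -> "TransferFunction":
        return cls(kind="tabulated_monotone",
                   table_x=np.asarray(inputs, dtype=float),
                   table_y=np.asarray(rates, dtype=float))


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation beyond the table ends."""
    x = np.asarray(x, dtype=float)
    flat = np.atleast_1d(x)
    out = np.interp(flat, xp, fp)
    lo = flat < xp[0]
    hi = flat > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        out[lo] = fp[0] + slope * (flat[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out[hi] = fp[-1] + slope * (flat[hi] - xp[-1])
    return out.reshape(x.shape)
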