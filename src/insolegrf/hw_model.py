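"""Block-oriented models for sensor-to-force estimation.

A multi-input Hammerstein-Wiener (HW) model maps the percent resistance
change of each plantar sensor through a static piecewise-linear input
nonlinearity and a discrete-time output-error transfer function, sums the
branch outputs, and passes the sum through a static piecewise-linear output
nonlinearity:

    yhat(k) = h( sum_i G_i(q) f_i(dR_i(k)) )

All linear blocks are strictly proper (minimum one-sample input delay):
the physical sensor-to-force path has no direct feedthrough.  Simulations
start from zero initial conditions; the first ``max(n_b, n_f)`` samples are
a transient burn-in region that metric computations may exclude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "TransferFunction",
    "PiecewiseLinear",
    "HWModel",
    "LinearModel",
    "pwl_eval",
    "tf_simulate",
    "static_gain",
    "hw_simulate",
    "linear_simulate",
]


@dataclass
class TransferFunction:
    """Strictly proper discrete transfer function G(q) = B(q)/F(q).

    ``b`` holds the ``n_b`` numerator coefficients acting on inputs delayed
    by 1..n_b samples; ``f`` holds the monic denominator ``[1, f_1..f_nf]``
    acting on past outputs.
    """

    b: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if self.b.size < 1:
            raise ValueError("numerator needs at least one coefficient")
        if self.f.size < 1 or self.f[0] != 1.0:
            raise ValueError("denominator must be monic ([1, f1, ...])")
        if not (np.all(np.isfinite(self.b)) and np.all(np.isfinite(self.f))):
            raise ValueError("coefficients must be finite")

    @property
    def n_b(self) -> int:
        return int(self.b.size)

    @property
    def n_f(self) -> int:
        return int(self.f.size - 1)

    def is_stable(self) -> bool:
        if self.n_f == 0:
            return True
        roots = np.roots(self.f)
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class PiecewiseLinear:
    """Continuous piecewise-linear map defined by knots.

    Between breakpoints the map interpolates linearly; outside the knot
    range it extrapolates with the configured end slopes (by default the
    slopes of the terminal segments), keeping gradients alive far from the
    data instead of going flat.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    end_slopes: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.size < 2:
            raise ValueError("need at least two breakpoints")
        if self.breakpoints.size != self.values.size:
            raise ValueError("breakpoints and values must have equal length")
        if not np.all(np.diff(self.breakpoints) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.end_slopes is None:
            db = np.diff(self.breakpoints)
            dv = np.diff(self.values)
            self.end_slopes = (float(dv[0] / db[0]), float(dv[-1] / db[-1]))

    @classmethod
    def identity(cls, breakpoints: np.ndarray) -> "PiecewiseLinear":
        bp = np.asarray(breakpoints, dtype=float)
        return cls(bp, bp.copy(), end_slopes=(1.0, 1.0))


def pwl_eval(nl: PiecewiseLinear, x):
    """Evaluate a piecewise-linear map at scalar or array ``x``."""
    x_arr = np.asarray(x, dtype=float)
    bp, vals = nl.breakpoints, nl.values
    y = np.interp(x_arr, bp, vals)
    sl, sr = nl.end_slopes
    below = x_arr < bp[0]
    above = x_arr > bp[-1]
    if np.any(below):
        y = np.where(below, vals[0] + sl * (x_arr - bp[0]), y)
    if np.any(above):
        y = np.where(above, vals[-1] + sr * (x_arr - bp[-1]), y)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(y)
    return y


def _tf_filter(b: np.ndarray, f: np.ndarray, u: np.ndarray) -> np.ndarray:
    # strictly proper: numerator shifted by one sample
    num = np.concatenate(([0.0], b))
    return lfilter(num, f, u)


def tf_simulate(tf: TransferFunction, u: np.ndarray, check_stability: bool = True) -> np.ndarray:
    """Free-run simulation with zero initial conditions.

    y(k) = sum_j b[j] u(k-1-j) - sum_m f[m] y(k-m).
    Emits a warning (but still simulates) when the denominator has a root
    on or outside the unit circle.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("input must be finite")
    if check_stability and not tf.is_stable():
        warnings.warn("transfer function has a pole on/outside the unit circle", RuntimeWarning)
    return _tf_filter(tf.b, tf.f, u)


def static_gain(tf: TransferFunction) -> float:
    """DC gain sum(b)/sum(f); errors on an integrator (sum(f) = 0)."""
    denom = float(np.sum(tf.f))
    if denom == 0.0:
        raise ZeroDivisionError("static gain undefined: denominator sums to zero (integrator)")
    return float(np.sum(tf.b)) / denom


CHANNELS = ("TO", "MT", "MF", "HL")
AXES = ("vertical", "mediolateral", "anteroposterior")


@dataclass
class HWModel:
    """MISO Hammerstein-Wiener model for one GRF axis."""

    axis: str
    channels: tuple[str, ...]
    input_nl: dict[str, PiecewiseLinear]
    linear: dict[str, TransferFunction]
    output_nl: PiecewiseLinear

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        if set(self.input_nl) != set(self.channels) or set(self.linear) != set(self.channels):
            raise ValueError("input_nl and linear must cover exactly the model channels")

    @property
    def burn_in(self) -> int:
        return max(max(g.n_b, g.n_f) for g in self.linear.values())

    def orders(self) -> tuple[int, int]:
        g = self.linear[self.channels[0]]
        return g.n_b, g.n_f


@dataclass
class LinearModel:
    """MISO output-error linear model for one GRF axis."""

    axis: str
    channels: tuple[str, ...]
    linear: dict[str, TransferFunction]

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        if set(self.linear) != set(self.channels):
            raise ValueError("linear blocks must cover exactly the model channels")

    @property
    def burn_in(self) -> int:
        return max(max(g.n_b, g.n_f) for g in self.linear.values())

    def orders(self) -> tuple[int, int]:
        g = self.linear[self.channels[0]]
        return g.n_b, g.n_f


def _check_inputs(channels: tuple[str, ...], inputs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if set(inputs) != set(channels):
        raise ValueError(
            f"channel mismatch: model has {sorted(channels)}, inputs have {sorted(inputs)}"
        )
    arrs = {c: np.asarray(inputs[c], dtype=float) for c in channels}
    lengths = {a.size for a in arrs.values()}
    if len(lengths) != 1:
        raise ValueError("all channel series must share one length")
    return arrs


def hw_simulate(model: HWModel, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Simulate yhat(k) = h( sum_i G_i(q) f_i(dR_i(k)) )."""
    arrs = _check_inputs(model.channels, inputs)
    z = None
    for c in model.channels:
        branch = _tf_filter(
            model.linear[c].b, model.linear[c].f, pwl_eval(model.input_nl[c], arrs[c])
        )
        z = branch if z is None else z + branch
    return pwl_eval(model.output_nl, z)


def linear_simulate(model: LinearModel, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Simulate the MISO linear model yhat(k) = sum_i G_i(q) dR_i(k)."""
    arrs = _check_inputs(model.channels, inputs)
    y = None
    for c in model.channels:
        branch = _tf_filter(model.linear[c].b, model.linear[c].f, arrs[c])
        y = branch if y is None else y + branch
    return y
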