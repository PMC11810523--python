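"""Cyclic compression-test analysis for a single piezoresistive sensor.

Repeated loading of the porous sensor produces hysteresis loops in the
force vs. percent-resistance-change plane.  Each loading branch is fitted
with a saturating exponential

    dR(F) = -A * (1 - exp(-F / f0)) + offset

whose slope is the sensor sensitivity and whose extrapolation to -100 %
resistance change gives the saturation force (the usable force range).
Peak forces relax viscoelastically over cycles toward a steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HysteresisLoop",
    "ExpFit",
    "split_cycles",
    "fit_exponential_response",
    "sensitivity_at",
    "extrapolate_saturation_force",
    "loop_area",
    "relaxation_summary",
]


@dataclass
class HysteresisLoop:
    """One load/unload cycle of the force vs. resistance-change trace."""

    cycle_index: int
    force: np.ndarray
    delta_r: np.ndarray
    loading: np.ndarray  # boolean mask: rising-force samples

    @property
    def loading_branch(self) -> tuple[np.ndarray, np.ndarray]:
        return self.force[self.loading], self.delta_r[self.loading]

    @property
    def unloading_branch(self) -> tuple[np.ndarray, np.ndarray]:
        return self.force[~self.loading], self.delta_r[~self.loading]


@dataclass(frozen=True)
class ExpFit:
    """Parameters of the saturating exponential force->dR fit."""

    amplitude: float  # A > 0: dR tends to offset - A as F -> inf
    rate_force: float  # f0 > 0, newtons: e-folding force
    offset: float  # percent: dR at zero force
    residual_rms: float

    def predict(self, force):
        f = np.asarray(force, dtype=float)
        out = -self.amplitude * (1.0 - np.exp(-f / self.rate_force)) + self.offset
        return float(out) if np.isscalar(force) else out


def split_cycles(
    force: np.ndarray, delta_r: np.ndarray, period_samples: int
) -> list[HysteresisLoop]:
    """Split a cyclic trace into loops at force minima near period multiples.

    The split point for cycle boundary j is the force minimum within half a
    period of ``j * period_samples``; the loading branch is the rising-force
    segment of each loop.
    """
    force = np.asarray(force, dtype=float)
    delta_r = np.asarray(delta_r, dtype=float)
    if force.size != delta_r.size:
        raise ValueError("force and delta_r must have equal length")
    if period_samples < 4:
        raise ValueError("period must span at least 4 samples")
    n = force.size
    if n < period_samples:
        return []
    if np.ptp(force) == 0.0:
        return []
    half = period_samples // 2
    bounds = [0]
    j = 1
    while j * period_samples < n:
        center = j * period_samples
        lo = max(bounds[-1] + 1, center - half)
        hi = min(n, center + half + 1)
        bounds.append(lo + int(np.argmin(force[lo:hi])))
        j += 1
    bounds.append(n)
    loops = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a < 4:
            continue
        f_seg = force[a:b]
        d_seg = delta_r[a:b]
        rising = np.empty(f_seg.size, dtype=bool)
        rising[:-1] = np.diff(f_seg) > 0
        rising[-1] = False
        loops.append(
            HysteresisLoop(cycle_index=i, force=f_seg, delta_r=d_seg, loading=rising)
        )
    return loops


def fit_exponential_response(force: np.ndarray, delta_r: np.ndarray) -> ExpFit:
    """Least-squares fit of dR(F) = -A(1 - exp(-F/f0)) + offset.

    Deterministic starting values: A = -min(dR), f0 = half the force range,
    offset = dR at the smallest force.
    """
    f = np.asarray(force, dtype=float)
    d = np.asarray(delta_r, dtype=float)
    if f.size < 4:
        raise ValueError("need at least 4 points")
    span = float(np.ptp(f))
    if span <= 0:
        raise ValueError("force must span a positive range")
    a0 = max(-float(np.min(d)), 1e-3)
    f00 = span / 2.0
    off0 = float(d[np.argmin(f)])

    def resid(p):
        a, f0, off = p
        return -a * (1.0 - np.exp(-f / f0)) + off - d

    sol = least_squares(
        resid,
        x0=[a0, f00, off0],
        bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"exponential fit did not converge (residual rms "
            f"{np.sqrt(np.mean(sol.fun**2)):.3g})"
        )
    a, f0, off = sol.x
    return ExpFit(
        amplitude=float(a),
        rate_force=float(f0),
        offset=float(off),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def sensitivity_at(fit: ExpFit, force: float) -> float:
    """Sensor sensitivity: slope of the fitted curve, -(A/f0) exp(-F/f0).

    Largest in magnitude at zero force (pore buckling gives big contact
    changes early) and decaying toward saturation.
    """
    if force < 0:
        raise ValueError("force must be non-negative")
    return -(fit.amplitude / fit.rate_force) * math.exp(-force / fit.rate_force)


def extrapolate_saturation_force(fit: ExpFit) -> float:
    """Force at which the fitted curve reaches -100 % resistance change.

    Solves -A(1 - exp(-F/f0)) + offset = -100.  When the asymptote
    (offset - A) never reaches -100 the saturation point is unreachable
    and ``math.inf`` is returned as a marker (not an exception).
    """
    frac = (100.0 + fit.offset) / fit.amplitude
    if frac >= 1.0:
        return math.inf
    return -fit.rate_force * math.log(1.0 - frac)


def loop_area(loop: HysteresisLoop) -> float:
    """Hysteresis area: loading-branch integral of dR dF minus unloading's.

    Computed as the closed-path trapezoidal integral of dR over force,
    traversed load-then-unload; positive when the loading branch sits
    above the unloading branch (the lagging sensor's loop orientation).
    """
    f = np.append(loop.force, loop.force[0])
    d = np.append(loop.delta_r, loop.delta_r[0])
    return float(np.sum(0.5 * (d[:-1] + d[1:]) * np.diff(f)))


def relaxation_summary(peak_forces: np.ndarray, band: float = 0.02) -> dict:
    """Peak-force relaxation: steady-state value and settling cycle.

    Steady state is the mean of the final 10 % of per-cycle peaks; the
    settling index is the first cycle whose peak lies within ``band``
    (relative) of that steady state.
    """
    peaks = np.asarray(peak_forces, dtype=float)
    if peaks.size < 10:
        raise ValueError("need at least 10 cycles")
    tail = peaks[-max(1, peaks.size // 10):]
    steady = float(np.mean(tail))
    within = np.abs(peaks - steady) <= band * abs(steady)
    settling = int(np.argmax(within)) if np.any(within) else int(peaks.size - 1)
    return {"steady_state_value": steady, "settling_cycle_index": settling}
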