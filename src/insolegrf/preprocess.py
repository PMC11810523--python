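"""Raw-signal conditioning: divider inversion, resistance change, detrending.

The insole sensors sit on the grounded side of a voltage divider (bias
resistor R_b = 560 ohm, 5 V supply), so the sensor resistance follows from
the measured output voltage as R = R_b * V_out / (V_in - V_out).  Force
estimation then works on the percent resistance change relative to the
zero-load (swing-phase) resistance, and on signals detrended (mean and
linear drift removed) per channel per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeasurementCircuit",
    "ResistanceTrace",
    "TrendRecord",
    "voltage_to_resistance",
    "resistance_to_voltage",
    "resistance_change",
    "estimate_zero_load_resistance",
    "detrend",
    "retrend",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class MeasurementCircuit:
    """Voltage-divider readout: supply ``v_in`` and bias resistor ``r_bias``."""

    v_in: float = 5.0
    r_bias: float = 560.0

    def __post_init__(self) -> None:
        if self.v_in <= 0:
            raise ValueError("v_in must be positive")
        if self.r_bias <= 0:
            raise ValueError("r_bias must be positive")


@dataclass
class ResistanceTrace:
    """Per-sample resistance with its zero-load reference and percent change."""

    resistance: np.ndarray
    r0: float
    delta_r: np.ndarray


@dataclass(frozen=True)
class TrendRecord:
    """Mean and per-sample OLS slope removed from a signal (for re-adding)."""

    mean: float
    slope: float


def voltage_to_resistance(v_out, circuit: MeasurementCircuit = MeasurementCircuit()):
    """Invert the low-side divider: R = r_bias * v_out / (v_in - v_out)."""
    v = np.asarray(v_out, dtype=float)
    if np.any(v < 0):
        raise ValueError("v_out must be non-negative")
    if np.any(v >= circuit.v_in):
        raise ValueError("v_out must be strictly below v_in (open circuit / saturated ADC)")
    r = circuit.r_bias * v / (circuit.v_in - v)
    return float(r) if np.isscalar(v_out) else r


def resistance_to_voltage(r, circuit: MeasurementCircuit = MeasurementCircuit()):
    """Forward divider: V_out = v_in * R / (R + r_bias)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("resistance must be non-negative")
    v = circuit.v_in * r_arr / (r_arr + circuit.r_bias)
    return float(v) if np.isscalar(r) else v


def resistance_change(r, r0: float):
    """Percent change 100 * (R - R0) / R0; bounded below by -100 for R >= 0."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("resistance must be non-negative")
    dr = 100.0 * (r_arr - r0) / r0
    return float(dr) if np.isscalar(r) else dr


def estimate_zero_load_resistance(
    resistance: np.ndarray,
    vertical_grf: np.ndarray | None = None,
    body_mass: float | None = None,
    unload_threshold: float = 0.02,
    percentile: float = 99.0,
) -> float:
    """Estimate the swing-phase (zero-load) resistance R0.

    With a synchronized vertical GRF, R0 is the median resistance over
    samples where the vertical force is below ``unload_threshold`` body
    weights (the foot is in the air).  Without one, falls back to a high
    percentile of the trace: unloading raises resistance, so the swing
    plateau sits near the top of the distribution.
    """
    r = np.asarray(resistance, dtype=float)
    if r.size == 0:
        raise ValueError("resistance series is empty")
    if vertical_grf is not None:
        if body_mass is None or body_mass <= 0:
            raise ValueError("body_mass required (and positive) when vertical_grf is given")
        mask = np.asarray(vertical_grf, dtype=float) < unload_threshold * body_mass * STANDARD_GRAVITY
        if not np.any(mask):
            raise ValueError(
                "no samples below the unload threshold; "
                "call without vertical_grf to use the percentile fallback"
            )
        return float(np.median(r[mask]))
    # 'lower' keeps the estimate on the swing plateau when a small outlier
    # block sits exactly at the top of the distribution
    return float(np.percentile(r, percentile, method="lower"))


def detrend(series: np.ndarray) -> tuple[np.ndarray, TrendRecord]:
    """Remove the mean and OLS linear trend; return residual and trend record.

    The record lets callers add the trend back (the raw mean matters for
    plotting in physical units even though identification runs on centered
    signals).
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two samples to detrend")
    k = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(k, y, 1)
    resid = y - (intercept + slope * k)
    return resid, TrendRecord(mean=float(np.mean(y)), slope=float(slope))


def retrend(detrended: np.ndarray, trend: TrendRecord) -> np.ndarray:
    """Invert :func:`detrend`: add the removed line back."""
    y = np.asarray(detrended, dtype=float)
    k = np.arange(y.size, dtype=float)
    intercept = trend.mean - trend.slope * (y.size - 1) / 2.0
    return y + intercept + trend.slope * k
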