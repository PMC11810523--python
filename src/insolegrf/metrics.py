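"""Evaluation metrics: scaled RMS/MAE, R^2, body-weight normalization.

Percent errors are scaled by the maximum change (range) of the measured
body-weight-normalized force over the evaluation dataset, per axis, so that
participants of different mass are comparable:

    RMS% = 100 * sqrt(mean((y - yhat)^2)) / (max y - min y)
    MAE% = 100 * mean(|y - yhat|)        / (max y - min y)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .preprocess import STANDARD_GRAVITY

__all__ = [
    "FitReport",
    "bodyweight_normalize",
    "amplitude_scale",
    "scaled_rms",
    "scaled_mae",
    "r_squared",
    "fit_report",
]


@dataclass(frozen=True)
class FitReport:
    """All evaluation metrics for one model on one dataset."""

    rms_pct: float
    mae_pct: float
    r_squared: float
    rms_abs: float
    mae_abs: float
    n: int
    axis: str = ""
    evaluation_mode: str = "time_series"

    def to_row(self) -> dict:
        """One flat CSV-ready record."""
        return asdict(self)


def bodyweight_normalize(force, body_mass: float, g: float = STANDARD_GRAVITY):
    """Force in newtons -> body-weight (BW) units: F / (m * g)."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    out = np.asarray(force, dtype=float) / (body_mass * g)
    return float(out) if np.isscalar(force) else out


def amplitude_scale(y: np.ndarray) -> float:
    """Range max(y) - min(y); errors on a constant series."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two samples")
    scale = float(np.max(y) - np.min(y))
    if scale == 0.0:
        raise ValueError("degenerate scale: series is constant")
    return scale


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("empty series")
    return y, yhat


def scaled_rms(y, yhat, scale: float) -> float:
    y, yhat = _check_pair(y, yhat)
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 100.0 * float(np.sqrt(np.mean((y - yhat) ** 2))) / scale


def scaled_mae(y, yhat, scale: float) -> float:
    y, yhat = _check_pair(y, yhat)
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 100.0 * float(np.mean(np.abs(y - yhat))) / scale


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant measured series")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_report(
    y_measured_n: np.ndarray,
    yhat_n: np.ndarray,
    body_mass: float,
    axis: str = "",
    evaluation_mode: str = "time_series",
    burn_in: int = 10,
    scale: float | None = None,
) -> FitReport:
    """Aggregate metrics in scaled percent and newtons.

    ``burn_in`` initial samples (simulation transient from zero initial
    conditions) are excluded from every metric.  ``scale`` may be supplied
    to evaluate against an externally fixed amplitude (e.g. the raw
    time-series range when scoring segmented ensemble curves); by default
    it is the range of the burn-in-excluded measured BW signal.
    """
    y, yhat = _check_pair(y_measured_n, yhat_n)
    if burn_in < 0 or burn_in >= y.size - 1:
        raise ValueError("burn_in leaves fewer than 2 samples")
    y = y[burn_in:]
    yhat = yhat[burn_in:]
    y_bw = bodyweight_normalize(y, body_mass)
    yhat_bw = bodyweight_normalize(yhat, body_mass)
    if scale is None:
        scale = amplitude_scale(y_bw)
    return FitReport(
        rms_pct=scaled_rms(y_bw, yhat_bw, scale),
        mae_pct=scaled_mae(y_bw, yhat_bw, scale),
        r_squared=r_squared(y_bw, yhat_bw),
        rms_abs=float(np.sqrt(np.mean((y - yhat) ** 2))),
        mae_abs=float(np.mean(np.abs(y - yhat))),
        n=int(y.size),
        axis=axis,
        evaluation_mode=evaluation_mode,
    )
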