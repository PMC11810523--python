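"""Identification/validation datasets built from trials.

A :class:`Dataset` holds what the estimator sees: per-channel detrended
percent resistance changes (inputs), the detrended body-weight-normalized
GRF for one axis (output), and the amplitude of the raw BW-normalized
output used to scale percent error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hw_model import HWModel, LinearModel, hw_simulate, linear_simulate
from .metrics import amplitude_scale, bodyweight_normalize
from .preprocess import (
    MeasurementCircuit,
    detrend,
    estimate_zero_load_resistance,
    resistance_change,
    voltage_to_resistance,
)
from .trial_io import Trial

__all__ = ["Dataset", "trial_inputs", "prepare_dataset", "concat_datasets", "simulate_model"]


@dataclass
class Dataset:
    """Inputs/output pair for one GRF axis, ready for identification."""

    inputs: dict[str, np.ndarray]
    output: np.ndarray
    scale: float
    axis: str = ""
    role: str = "identification"

    def __post_init__(self) -> None:
        self.inputs = {c: np.asarray(v, dtype=float) for c, v in self.inputs.items()}
        self.output = np.asarray(self.output, dtype=float)
        lengths = {v.size for v in self.inputs.values()} | {self.output.size}
        if len(lengths) != 1:
            raise ValueError("all dataset series must share one length")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n(self) -> int:
        return int(self.output.size)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.inputs)


def trial_inputs(trial: Trial, circuit: MeasurementCircuit = MeasurementCircuit()) -> dict[str, np.ndarray]:
    """Voltages -> detrended percent resistance change, per channel.

    The zero-load resistance R0 is estimated per trial (swing-phase median,
    using the measured vertical GRF), so slow day-to-day baseline drift does
    not leak across trials.
    """
    out: dict[str, np.ndarray] = {}
    for c, v in trial.voltages.items():
        r = voltage_to_resistance(v, circuit)
        try:
            r0 = estimate_zero_load_resistance(
                r, vertical_grf=trial.grf["vertical"], body_mass=trial.body_mass
            )
        except ValueError:
            r0 = estimate_zero_load_resistance(r)
        dr = resistance_change(r, r0)
        out[c], _ = detrend(dr)
    return out


def prepare_dataset(
    trial: Trial,
    axis: str,
    role: str = "identification",
    circuit: MeasurementCircuit = MeasurementCircuit(),
) -> Dataset:
    """Build one axis' dataset from a trial (detrended inputs and output)."""
    inputs = trial_inputs(trial, circuit)
    y_bw = bodyweight_normalize(trial.grf[axis], trial.body_mass)
    scale = amplitude_scale(y_bw)
    y_det, _ = detrend(y_bw)
    return Dataset(inputs=inputs, output=y_det, scale=scale, axis=axis, role=role)


def concat_datasets(datasets: list[Dataset]) -> Dataset:
    """Concatenate per-trial datasets (each already detrended on its own)."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    channels = datasets[0].channels
    for d in datasets[1:]:
        if d.channels != channels or d.axis != datasets[0].axis:
            raise ValueError("datasets must share channels and axis")
    inputs = {c: np.concatenate([d.inputs[c] for d in datasets]) for c in channels}
    output = np.concatenate([d.output for d in datasets])
    scale = float(np.mean([d.scale for d in datasets]))
    return Dataset(inputs=inputs, output=output, scale=scale, axis=datasets[0].axis, role=datasets[0].role)


def simulate_model(model, dataset: Dataset) -> np.ndarray:
    """Free-run simulation of an HW or linear model on a dataset's inputs."""
    if isinstance(model, HWModel):
        return hw_simulate(model, dataset.inputs)
    if isinstance(model, LinearModel):
        return linear_simulate(model, dataset.inputs)
    raise TypeError(f"unsupported model type {type(model).__name__}")
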