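"""Reading, writing and aligning walking-trial data; model serialization.

CSV contract (comma-separated, header row):

* sensor table: ``time_s, v_TO, v_MT, v_MF, v_HL``  (volts)
* GRF table:    ``time_s, f_v, f_ml, f_ap``          (newtons)

``read_trial`` linearly interpolates both streams onto one uniform grid
spanning their time overlap, so sensor and force-plate streams recorded at
different rates land on a common clock.

Models are serialized as versioned JSON documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hw_model import (
    AXES,
    CHANNELS,
    HWModel,
    LinearModel,
    PiecewiseLinear,
    TransferFunction,
)

__all__ = ["Trial", "read_trial", "write_trial", "serialize_model", "deserialize_model"]

MODEL_SCHEMA_VERSION = 1

_SENSOR_COLS = {c: f"v_{c}" for c in CHANNELS}
_GRF_COLS = {"vertical": "f_v", "mediolateral": "f_ml", "anteroposterior": "f_ap"}
_TIME_COL = "time_s"


@dataclass
class Trial:
    """One walking trial: synchronized sensor voltages and 3-axis GRFs.

    All series share one uniform time grid; ``labels`` carries free-text
    metadata (participant id, day index, trial index).
    """

    time: np.ndarray
    voltages: dict[str, np.ndarray]
    grf: dict[str, np.ndarray]
    body_mass: float
    sample_rate: float
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltages = {c: np.asarray(v, dtype=float) for c, v in self.voltages.items()}
        self.grf = {a: np.asarray(v, dtype=float) for a, v in self.grf.items()}
        n = self.time.size
        if n < 2:
            raise ValueError("trial needs at least two samples")
        for name, series in list(self.voltages.items()) + list(self.grf.items()):
            if series.size != n:
                raise ValueError(f"series '{name}' length {series.size} != time length {n}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        step = (self.time[-1] - self.time[0]) / (n - 1)
        if np.max(np.abs(dt - step)) > 1e-9 * max(abs(step), 1.0):
            raise ValueError("time grid must be uniform")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.voltages)


def _load_table(path, required: dict[str, str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if _TIME_COL not in df.columns:
        raise ValueError(f"{what} table {path} lacks time column '{_TIME_COL}'")
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise ValueError(f"{what} table {path} lacks column(s): {', '.join(missing)}")
    if len(df) < 2:
        raise ValueError(f"{what} table {path} needs at least 2 rows")
    t = df[_TIME_COL].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{what} table {path} has non-monotonic time")
    return df


def read_trial(
    sensor_table,
    grf_table,
    body_mass: float,
    target_rate: float = 100.0,
    labels: dict[str, str] | None = None,
) -> Trial:
    """Read sensor + GRF CSVs and align them onto a uniform common grid."""
    sens = _load_table(sensor_table, _SENSOR_COLS, "sensor")
    grf = _load_table(grf_table, _GRF_COLS, "GRF")
    ts = sens[_TIME_COL].to_numpy(dtype=float)
    tg = grf[_TIME_COL].to_numpy(dtype=float)
    t0 = max(ts[0], tg[0])
    t1 = min(ts[-1], tg[-1])
    if t1 <= t0:
        raise ValueError("sensor and GRF streams have no time overlap")
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate
    voltages = {
        c: np.interp(grid, ts, sens[col].to_numpy(dtype=float)) for c, col in _SENSOR_COLS.items()
    }
    forces = {
        a: np.interp(grid, tg, grf[col].to_numpy(dtype=float)) for a, col in _GRF_COLS.items()
    }
    return Trial(
        time=grid,
        voltages=voltages,
        grf=forces,
        body_mass=body_mass,
        sample_rate=target_rate,
        labels=dict(labels or {}),
    )


def write_trial(trial: Trial, sensor_path, grf_path) -> None:
    """Write a trial back to the two-CSV contract (with a metadata sidecar).

    Metadata (body mass, sample rate, labels) goes to
    ``<sensor_path>.meta.json`` so the CSVs stay plain tables.
    """
    sens = pd.DataFrame({_TIME_COL: trial.time})
    for c, col in _SENSOR_COLS.items():
        sens[col] = trial.voltages[c]
    grf = pd.DataFrame({_TIME_COL: trial.time})
    for a, col in _GRF_COLS.items():
        grf[col] = trial.grf[a]
    sens.to_csv(sensor_path, index=False, float_format="%.12g")
    grf.to_csv(grf_path, index=False, float_format="%.12g")
    meta = {
        "body_mass": trial.body_mass,
        "sample_rate": trial.sample_rate,
        "labels": trial.labels,
    }
    Path(str(sensor_path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trial_meta(sensor_path) -> dict:
    """Load the metadata sidecar written by :func:`write_trial`."""
    return json.loads(Path(str(sensor_path) + ".meta.json").read_text())


def _tf_to_dict(tf: TransferFunction) -> dict:
    return {"b": tf.b.tolist(), "f": tf.f.tolist()}


def _tf_from_dict(d: dict) -> TransferFunction:
    return TransferFunction(np.asarray(d["b"]), np.asarray(d["f"]))


def _pwl_to_dict(nl: PiecewiseLinear) -> dict:
    return {
        "breakpoints": nl.breakpoints.tolist(),
        "values": nl.values.tolist(),
        "end_slopes": list(nl.end_slopes),
    }


def _pwl_from_dict(d: dict) -> PiecewiseLinear:
    return PiecewiseLinear(
        np.asarray(d["breakpoints"]), np.asarray(d["values"]), tuple(d["end_slopes"])
    )


def serialize_model(model, path) -> None:
    """Write an HW or linear model to a versioned JSON document."""
    if isinstance(model, HWModel):
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "class": "hw",
            "axis": model.axis,
            "channels": list(model.channels),
            "input_nl": {c: _pwl_to_dict(model.input_nl[c]) for c in model.channels},
            "linear": {c: _tf_to_dict(model.linear[c]) for c in model.channels},
            "output_nl": _pwl_to_dict(model.output_nl),
        }
    elif isinstance(model, LinearModel):
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "class": "linear",
            "axis": model.axis,
            "channels": list(model.channels),
            "linear": {c: _tf_to_dict(model.linear[c]) for c in model.channels},
        }
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1))


def deserialize_model(path, expect: str | None = None):
    """Load a model written by :func:`serialize_model`.

    ``expect`` ('hw' or 'linear') asserts the stored class tag.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unknown model schema version {version!r}")
    cls = doc.get("class")
    if expect is not None and cls != expect:
        raise ValueError(f"expected a {expect!r} model, file holds {cls!r}")
    channels = tuple(doc["channels"])
    linear = {c: _tf_from_dict(doc["linear"][c]) for c in channels}
    if cls == "hw":
        return HWModel(
            axis=doc["axis"],
            channels=channels,
            input_nl={c: _pwl_from_dict(doc["input_nl"][c]) for c in channels},
            linear=linear,
            output_nl=_pwl_from_dict(doc["output_nl"]),
        )
    if cls == "linear":
        return LinearModel(axis=doc["axis"], channels=channels, linear=linear)
    raise ValueError(f"unknown model class tag {cls!r}")
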