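"""Prepackaged synthetic studies: model-class comparison and multiday drift.

These reproduce, on synthetic data, the two headline observations the
pipeline is built around: (i) Hammerstein-Wiener models outperform linear
models on every GRF axis when the sensors are nonlinear and hysteretic,
and (ii) a model identified on day 0 degrades as the sensors drift over
subsequent days.

Problem sizes are deliberately moderate (shortened speed plateaus, 50 Hz
grid, reduced order grids) so a full study runs in minutes on one core;
the statistical structure of the full protocol is preserved.
"""

from __future__ import annotations

import numpy as np

from .datasets import concat_datasets, prepare_dataset
from .hw_model import AXES
from .identify import IdentifyConfig, OrderGrid, evaluate_model, fit_hw, identify_participant
from .synth import GaitConfig, default_sensor_params, generate_session, generate_trial

__all__ = ["study_gait_config", "headline_comparison", "drift_study"]


def study_gait_config(plateau_s: float = 12.0, sample_rate: float = 50.0) -> GaitConfig:
    """Trapezoidal 2.5/3/3.5/3/2.5 km/h protocol with configurable plateaus."""
    profile = tuple((s, plateau_s) for s in (2.5, 3.0, 3.5, 3.0, 2.5))
    return GaitConfig(speed_profile=profile, sample_rate=sample_rate)


def headline_comparison(
    seed: int = 42,
    plateau_s: float = 12.0,
    sample_rate: float = 50.0,
    hw_grid: OrderGrid = OrderGrid((1, 3), (1, 2)),
    linear_grid: OrderGrid = OrderGrid((1, 4), (1, 4)),
    max_iter: int = 60,
):
    """Identify HW and linear models on one synthetic participant.

    Three trials are generated (two identification, one validation) with
    the default nonlinear hysteretic sensors; both model classes run their
    order search per axis.  Returns the :class:`ParticipantResult`.
    """
    gait = study_gait_config(plateau_s, sample_rate)
    trials = [
        generate_trial(gait, seed=np.random.SeedSequence([seed, j]),
                       labels={"trial": str(j + 1)})[0]
        for j in range(3)
    ]
    config = IdentifyConfig(
        linear_grid=linear_grid, hw_grid=hw_grid, seed=seed, max_iter=max_iter
    )
    return identify_participant(trials, config)


def drift_study(
    seed: int = 42,
    n_replicates: int = 10,
    days: tuple[int, ...] = (0, 1, 7),
    axis: str = "vertical",
    plateau_s: float = 8.0,
    sample_rate: float = 50.0,
    n_b: int = 2,
    n_f: int = 2,
    max_iter: int = 40,
) -> dict[int, float]:
    """Median validation RMS per day for day-0-identified HW models.

    Each replicate generates a three-day session with drifting sensor
    parameters, fits one HW model (fixed small order) on day-0 trials 1-2,
    and scores it on trial 3 of every day.  Returns the median scaled-RMS
    (percent) per day across replicates.
    """
    gait = study_gait_config(plateau_s, sample_rate)
    per_day: dict[int, list[float]] = {d: [] for d in days}
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)
        session = generate_session(days=days, gait=gait, seed=rep_seed)
        day0 = [t for t, _ in session[days[0]]]
        ds_id = concat_datasets(
            [prepare_dataset(t, axis, "identification") for t in day0[:2]]
        )
        model, _ = fit_hw(ds_id, n_b, n_f, seed=rep_seed, max_iter=max_iter)
        for day in days:
            val_trial = session[day][2][0]
            ds_val = prepare_dataset(val_trial, axis, "validation")
            per_day[day].append(evaluate_model(model, ds_val, val_trial.body_mass).rms_pct)
    return {d: float(np.median(v)) for d, v in per_day.items()}
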