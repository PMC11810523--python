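"""Multiday drift: how a day-0 model degrades as the sensors age.

Generates a three-day session in which the sensor parameters creep
(capacitive-like charging scales the baseline resistance and the
half-saturation force), fits one HW model on day-0 data, and scores it on
the held-out trial of each day.
"""

from insolegrf import fit_hw
from insolegrf.datasets import concat_datasets, prepare_dataset
from insolegrf.identify import evaluate_model
from insolegrf.studies import study_gait_config
from insolegrf.synth import generate_session

gait = study_gait_config(plateau_s=8.0, sample_rate=50.0)
session = generate_session(days=(0, 1, 7), gait=gait, seed=11)

day0 = [t for t, _ in session[0]]
ds_id = concat_datasets([prepare_dataset(t, "vertical") for t in day0[:2]])
model, _ = fit_hw(ds_id, 2, 2, seed=0)

for day in (0, 1, 7):
    val = session[day][2][0]
    rep = evaluate_model(model, prepare_dataset(val, "vertical"), val.body_mass)
    print(f"day {day}: validation RMS {rep.rms_pct:5.2f} %  "
          f"MAE {rep.mae_pct:5.2f} %  R2 {rep.r_squared:.3f}")

# Per-trial re-estimation of the zero-load resistance absorbs the baseline
# drift, but the shifted half-saturation force changes the sensor's gain
# curve, so estimation error grows with the days since identification.
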