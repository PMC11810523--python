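"""Analyze a cyclic compression test: hysteresis, sensitivity, saturation.

Simulates repeated 5-mm compressions of the heel sensor, splits the trace
into loops, fits the exponential force-to-resistance-change curve on the
loading branch, and extrapolates the usable force range.
"""

import numpy as np

from insolegrf import (
    extrapolate_saturation_force,
    fit_exponential_response,
    generate_cyclic_test,
    sensitivity_at,
    split_cycles,
)
from insolegrf.cyclic import loop_area, relaxation_summary

res = generate_cyclic_test(n_cycles=200, seed=3)
loops = split_cycles(res["force"], res["delta_r"], res["period_samples"])
peaks = np.array([lp.force.max() for lp in loops])
relax = relaxation_summary(peaks)
print(f"{len(loops)} cycles; peak force relaxes from {peaks[0]:.0f} N to "
      f"{relax['steady_state_value']:.0f} N "
      f"(settled by cycle {relax['settling_cycle_index']})")

for name, loop in (("first", loops[0]), ("last", loops[-1])):
    f, d = loop.loading_branch
    mask = f <= 300.0  # calibrate on the sub-saturation regime
    fit = fit_exponential_response(f[mask], d[mask])
    sat = extrapolate_saturation_force(fit)
    print(f"{name:>5s} cycle: sensitivity at 0 N {sensitivity_at(fit, 0.0):7.3f} %/N, "
          f"at 200 N {sensitivity_at(fit, 200.0):7.3f} %/N, "
          f"extrapolated saturation force {sat:6.0f} N, "
          f"hysteresis area {loop_area(loop):8.0f} N*%")

# Sensitivity (curve slope) is largest at low force where pores buckle and
# decays toward saturation; the -100 % extrapolation estimates the force
# at which the sensor would exhaust its resistance range.
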