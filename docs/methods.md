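# Methods

## Signal model and readout

Each insole sensor is a piezoresistive element read through a voltage
divider: the sensor sits on the grounded side, a bias resistor
`R_b = 560 Ω` on the supply side (`V_in = 5 V`), so the inversion is
`R = R_b · V_out / (V_in − V_out)`. The working quantity is the percent
resistance change `ΔR = 100 (R − R₀)/R₀` against the zero-load resistance
`R₀`, bounded below by −100 %.

`R₀` is estimated **per trial** as the median resistance over samples in
which the measured vertical force is below 2 % of body weight (the foot
is in the air); without a synchronized force signal the fallback is the
99th percentile of the resistance trace (unloading raises resistance).
The per-trial baseline deliberately absorbs slow day-to-day drift of the
unloaded resistance, so multiday degradation is driven by changes in the
sensor's force response rather than by a stale baseline.

Before identification, each trial's `ΔR` channels and body-weight (BW)
normalized GRFs are detrended independently (mean plus ordinary
least-squares line removed). Validation trials are detrended with their
own trends, never with those of the identification data: drift is
trial-specific. The removed trend is recorded so signals can be restored
for plotting.

## Model classes

For each GRF axis (vertical, mediolateral, anteroposterior) a
multi-input–single-output model maps the four `ΔR` channels to force:

* **Linear (output-error)**: `ŷ = Σᵢ Gᵢ(q) ΔRᵢ`, with
  `Gᵢ = Bᵢ(q)/Fᵢ(q)` discrete transfer functions.
* **Hammerstein–Wiener**: `ŷ = h( Σᵢ Gᵢ(q) fᵢ(ΔRᵢ) )`, adding one
  continuous piecewise-linear (PWL) input map per sensor and one shared
  PWL output map, ten breakpoints each.

All blocks are strictly proper (one-sample minimum input delay): the
physical sensor-to-force path has no feedthrough, and "causal"
combinations are read as `n_b ≤ n_f`. Simulations start from zero initial
conditions; the first `max(n_b, n_f)` samples are a burn-in transient
excluded from fitting and metrics (default 10 samples where no model
context is available). PWL maps extrapolate with their end-segment slopes
rather than constants, keeping gradients alive outside the knot range
during optimization.

### Identifiability

The HW parameterization has a gain ambiguity per branch (`c·fᵢ` with
`Gᵢ/c` is simulation-equivalent). Returned models are canonicalized to
unit static gain per linear block, the channel gain living in the input
PWL. The offset ambiguity between input ordinates and the output map is
only asymptotic — a constant shift passes through the filters with a
transient — so it is weakly identifiable and no offset anchoring is
applied; an earlier design that re-anchored `h` through (0, 0) was
dropped because the shift is not exactly simulation-equivalent.

## Estimation

Both classes are fitted by prediction-error minimization on the
**simulated (free-run) response**, not one-step-ahead prediction,
matching the output-error structure. The optimizer is a trust-region
least-squares (`scipy.optimize.least_squares`, method `trf`) with
analytic Jacobians:

* input-PWL ordinates enter linearly before the filters (hat-basis
  columns filtered through `Gᵢ`),
* filter coefficients follow the classic output-error derivative
  filters (`∂ŷ/∂b` via `u/F`, `∂ŷ/∂f` via `−ŷᵢ/F`),
* the chain rule through the output map multiplies by the local slope
  `h′(z)`; output ordinates contribute their hat basis directly.

Starting values: an equation-error (ARX) least-squares solution with a
shared denominator, radially stabilized, initializes the linear fit; the
HW fit starts from the linear fit wrapped in identity nonlinearities
(restart 1) and from seeded `N(0, 0.1·range)` perturbations of the PWL
ordinates (restart 2, mirroring the two-restart protocol); the restart
with the lower identification RMS wins. Breakpoint abscissae are frozen
at uniform spacing over the 1st–99th percentile range of the
identification inputs (output knots over the range of the linear-pass
intermediate signal); only ordinates are optimized, which keeps every fit
reproducible. Tolerances: relative cost 1e-8, step 1e-10; the iteration
budget (default 200 outer iterations) bounds each candidate in the order
search. Unstable candidates are not rejected — their exploding free-run
residuals are clamped to a large finite value so the trust region backs
off, and a model with poles on or outside the unit circle simply scores
badly on validation.

## Order search and selection

Orders are shared across the four inputs. The brute-force grids are 1–8
poles × 1–5 zeros (HW) and all causal combinations to 10 poles (linear).
Every admissible `(n_b, n_f)` is fitted on the identification data
(trials 1–2 concatenated) and scored on the held-out third trial; the
lowest validation scaled-RMS wins, ties broken by fewer parameters, then
fewer poles. Selection can alternatively score candidates on segmented
ensemble curves (`selection="segmented"`), since the best order for
time-series tracking and for cycle-averaged curves need not coincide; the
default selects on the time series and reports both modes.

## Metrics

Percent errors are scaled by the **range** (max − min) of the measured
BW-normalized force over the evaluation dataset, per axis — the literal
reading of "maximum change" — with `g = 9.81 m/s²`:

```
RMS% = 100 · sqrt(mean((y − ŷ)²)) / (max y − min y)
MAE% = 100 · mean(|y − ŷ|)        / (max y − min y)
```

R² is computed on the same burn-in-excluded samples. Segmented reports
use the same time-series denominator so the two modes are directly
comparable; the segmented curves themselves are raw ensemble means (the
optional smoothing spline is display-only and never enters metrics).

## Gait segmentation

Heel strikes are rising crossings of 5 % body weight on the measured
vertical GRF with a 0.4 s refractory period; events always come from the
measured signal, for both measured and estimated curves. Cycles are
linearly resampled to a 101-point 0–100 % phase grid (the biomechanics
convention); cycles shorter than 0.4 s or longer than 2.5 s are
discarded. Ensembles report the per-phase mean and standard error
(`sd/√n`).

## Cyclic-test analysis

Hysteresis loops are split at force minima near period multiples; the
loading branch is the rising-force segment. The calibration curve is the
three-parameter saturating exponential `ΔR(F) = −A(1 − e^{−F/f₀}) + c`
(the form consistent with an asymptotic floor and a −100 % extrapolation),
fitted with deterministic starting values (`A = −min ΔR`, `f₀` = half the
force range, `c = ΔR` at the smallest force). Sensitivity is the analytic
slope `−(A/f₀)e^{−F/f₀}`; the saturation force solves the fitted curve
for −100 % and returns an `inf` marker when the asymptote `c − A` never
reaches it. Peak-force relaxation is summarized by the mean of the final
10 % of per-cycle peaks and the first cycle within 2 % of that value.
In the acceptance study the exponential is fitted on the sub-saturation
part of the loading branch (forces ≤ 300 N): the synthetic sensor's true
floor is −90 %, so a fit over the full range correctly reports the
−100 % point as unreachable, while the low-force fit mimics a
calibration that extrapolates the usable range from the regime where the
curve is still informative.

## Synthetic data generator

The generator emulates the study conditions end to end; its defaults are
the study's conditions, not tuning knobs.

* **Protocol**: five speed plateaus (2.5, 3, 3.5, 3, 2.5 km/h) of 50 s
  each; speed modulates cadence (+4 steps/min per km/h around 90
  steps/min at 3 km/h) and vertical peak (+0.02 BW per km/h around
  1.15 BW). Body mass defaults to the study-population mean of 80.1 kg.
* **Waveforms**: one leg; stance (62 % of the cycle) alternates with
  swing where the vertical force is exactly zero. Vertical stance force
  is a double-bump curve, mediolateral a 0.07 BW half-sine, and
  anteroposterior a 0.18 BW braking/propulsion full sine whose per-cycle
  impulse cancels. Cycle durations carry 3 % coefficient-of-variation
  jitter.
* **Load distribution**: Gaussian activation bumps over stance phase
  (heel 15 %, midfoot 40 %, metatarsal 70 %, toe 88 %), normalized so the
  four site forces sum exactly to the vertical force.
* **Sensor physics**: static saturating law
  `ΔR*(F) = −90 · F/(F + f_half)` (Michaelis–Menten form, site-specific
  `f_half` of 90–160 N), first-order lag (τ = 50 ms) producing
  rate-dependent hysteresis, capacitive-like baseline creep (4 % of R₀,
  τ = 120 s), Gaussian readout noise (2 mV) and uniform mid-rise 16-bit
  quantization over 0–5 V. The static law is deliberately a different
  family from the exponential used in cyclic *fitting*, so the analysis
  operators are exercised under realistic model misspecification.
* **Multiday drift**: `f_half` and `R₀` scale by `(1 + 0.08)^days`,
  so day-0 models degrade on later days even though per-trial baseline
  estimation compensates the `R₀` part.
* **Cyclic test**: triangular 5-mm displacement at 800 mm/min through a
  standard-linear-solid viscoelastic force map (long-term stiffness
  100 N/mm, relaxing branch 40 N/mm, τ = 8 s), giving peak-force
  relaxation within the first ~30 s of cycling.

What the generator does **not** emulate: double support between two
insoles, biomechanically validated GRF waveform shapes, inter-participant
variability of foot geometry, electrode/wiring artifacts, and genuinely
unmodeled sensor aging. Passing tests therefore demonstrate that the
pipeline recovers models and reproduces the qualitative comparisons under
the assumed physics — not that the error percentages transfer to real
treadmill data.

## Study problem sizes

The prepackaged studies (`insolegrf.studies`) shorten the protocol to
keep a full run in minutes on one core while preserving its structure:
speed plateaus of 12 s (8 s for the drift study) on a 50 Hz grid, HW
order grid 1–3 poles × 1–2 zeros, linear grid to 4 poles, 60 outer
iterations per fit, and a fixed (2, 2)-order HW model for the ten drift
replicates. On these sizes the HW class beats the linear class on every
axis at the study seed, both classes sit well under 15 % validation RMS,
and day-0 models degrade monotonically over days 0 → 1 → 7 in the median.
The advantage of the HW class concentrates on the vertical axis, whose
heavy load drives the sensors deep into saturation; on the small-amplitude
shear axes, which stay in the sensors' near-linear regime, the two model
classes can score within a few tenths of a percent of each other at some
seeds.

## Known limitations

* The optimizer can stall in local minima for high HW orders; the
  two-restart protocol mitigates but does not eliminate this, and the
  order search treats a failed candidate as infinitely bad rather than
  retrying.
* Synchronization between sensor and force-plate streams assumes
  overlapping timestamps and linear interpolation; no lag estimation is
  performed.
* Segmented evaluation requires enough valid cycles; very short trials
  degrade the ensemble statistics.
* The exponential calibration form cannot represent the true
  Michaelis–Menten saturation exactly; fitted parameters are effective,
  range-dependent quantities, which is intrinsic to the analysis.
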