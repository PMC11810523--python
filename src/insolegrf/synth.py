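"""Synthetic walking trials, multiday sessions, and cyclic sensor tests.

The generator emulates the measurement conditions of a treadmill insole
study: trapezoidal speed profiles (2.5 -> 3.5 -> 2.5 km/h, ~50 s per
plateau), a heel-to-toe progression of plantar load across four sensor
sites, and a piezoresistive sensor whose percent resistance change
saturates near -90 % under maximal load, lags the applied force (rate-
dependent hysteresis), drifts slowly like a charging capacitor, and is
read through a 560-ohm voltage divider into a noisy 16-bit ADC.

Every stage returns its ground truth (events, per-site forces, noiseless
resistance change) so downstream estimators can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .preprocess import STANDARD_GRAVITY, MeasurementCircuit, resistance_to_voltage
from .trial_io import Trial

__all__ = [
    "GaitConfig",
    "SensorParams",
    "SiteWeights",
    "default_sensor_params",
    "generate_grf",
    "distribute_load",
    "sensor_forward",
    "generate_trial",
    "generate_session",
    "generate_cyclic_test",
]

SITES = ("TO", "MT", "MF", "HL")

#: Trapezoidal treadmill protocol: five plateaus of ~50 s each.
DEFAULT_SPEED_PROFILE = ((2.5, 50.0), (3.0, 50.0), (3.5, 50.0), (3.0, 50.0), (2.5, 50.0))


@dataclass
class GaitConfig:
    """Walking-trial generator settings.

    Cadence and vertical peak increase mildly with belt speed
    (+4 steps/min and +0.02 BW per km/h around the 3 km/h reference).
    """

    body_mass: float = 80.1  # kg, study-population mean
    cadence: float = 90.0  # steps/min at the 3 km/h reference speed
    speed_profile: tuple = DEFAULT_SPEED_PROFILE
    vertical_peak: float = 1.15  # BW
    ml_amplitude: float = 0.07  # BW
    ap_amplitude: float = 0.18  # BW
    cycle_variability: float = 0.03  # CV of cycle duration
    stance_fraction: float = 0.62
    sample_rate: float = 100.0  # Hz
    cadence_per_kmh: float = 4.0
    peak_per_kmh: float = 0.02
    reference_speed: float = 3.0  # km/h

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.sample_rate <= 0:
            raise ValueError("body_mass and sample_rate must be positive")
        for amp in (self.vertical_peak, self.ml_amplitude, self.ap_amplitude):
            if amp <= 0:
                raise ValueError("GRF amplitudes must be positive")
        for _, dur in self.speed_profile:
            if dur <= 0:
                raise ValueError("plateau durations must be positive")


@dataclass
class SensorParams:
    """Ground-truth physics of one synthetic piezoresistive sensor site."""

    r0: float = 2000.0  # ohm, zero-load resistance
    delta_r_max: float = 90.0  # percent: saturation floor magnitude
    f_half: float = 150.0  # N: force at half-saturation
    lag_tau: float = 0.05  # s: first-order lag -> hysteresis
    drift_magnitude: float = 4.0  # percent of r0, baseline creep amplitude
    drift_tau: float = 120.0  # s: baseline creep time constant
    noise_sd: float = 0.002  # V, additive readout noise
    adc_bits: int | None = 16  # None disables quantization
    day_drift_rate: float = 0.08  # fractional parameter drift per day

    def __post_init__(self) -> None:
        if not (0 < self.delta_r_max <= 100):
            raise ValueError("delta_r_max must lie in (0, 100]")
        if self.r0 <= 0 or self.f_half <= 0:
            raise ValueError("r0 and f_half must be positive")
        if self.lag_tau < 0 or self.drift_tau <= 0:
            raise ValueError("time constants must be non-negative (drift_tau positive)")

    def drifted(self, days: float) -> "SensorParams":
        """Parameters after ``days`` of capacitive-like charging drift."""
        g = (1.0 + self.day_drift_rate) ** days
        return replace(self, r0=self.r0 * g, f_half=self.f_half * g)


def default_sensor_params() -> dict[str, SensorParams]:
    """Per-site defaults; forward sites saturate at lower force (smaller pads)."""
    return {
        "TO": SensorParams(f_half=90.0),
        "MT": SensorParams(f_half=130.0),
        "MF": SensorParams(f_half=110.0),
        "HL": SensorParams(f_half=160.0),
    }


@dataclass
class SiteWeights:
    """Phase-dependent plantar load shares over 0-1 stance phase.

    Gaussian activation bumps ordered heel -> midfoot -> metatarsal -> toe,
    normalized so the four shares sum to one at every phase.
    """

    centers: dict[str, float] = field(
        default_factory=lambda: {"HL": 0.15, "MF": 0.40, "MT": 0.70, "TO": 0.88}
    )
    widths: dict[str, float] = field(
        default_factory=lambda: {"HL": 0.16, "MF": 0.20, "MT": 0.16, "TO": 0.12}
    )
    floor: float = 0.02

    def shares(self, phase: np.ndarray) -> dict[str, np.ndarray]:
        phase = np.asarray(phase, dtype=float)
        raw = {
            s: self.floor + np.exp(-0.5 * ((phase - self.centers[s]) / self.widths[s]) ** 2)
            for s in SITES
        }
        total = sum(raw.values())
        return {s: raw[s] / total for s in SITES}


def _vertical_shape(s: np.ndarray) -> np.ndarray:
    """Double-bump stance waveform on s in [0, 1), normalized to peak 1."""
    shape = np.sin(np.pi * s) * (1.0 + 0.4 * np.cos(2.0 * np.pi * s))
    # peak value of the analytic form, for normalization
    s_dense = np.linspace(0.0, 1.0, 2001)
    peak = np.max(np.sin(np.pi * s_dense) * (1.0 + 0.4 * np.cos(2.0 * np.pi * s_dense)))
    return shape / peak


def _speed_at(profile, t: float) -> float:
    acc = 0.0
    for speed, dur in profile:
        acc += dur
        if t < acc:
            return speed
    return profile[-1][0]


def generate_grf(config: GaitConfig, seed: int = 0):
    """Generate a 3-axis GRF trace (newtons) plus ground-truth heel strikes.

    One leg is simulated: stance alternates with swing (vertical force
    exactly zero in swing).  The vertical waveform shows the classic double
    bump; mediolateral is a half-sine weight-shift bump; anteroposterior is
    a braking/propulsion full sine whose per-cycle impulse cancels.
    """
    rng = np.random.default_rng(seed)
    rate = config.sample_rate
    total = sum(d for _, d in config.speed_profile)
    n = int(round(total * rate))
    bw = config.body_mass * STANDARD_GRAVITY
    fv = np.zeros(n)
    fml = np.zeros(n)
    fap = np.zeros(n)
    events: list[int] = []
    t = 0.0
    while t < total:
        speed = _speed_at(config.speed_profile, t)
        cadence = config.cadence + config.cadence_per_kmh * (speed - config.reference_speed)
        cycle = (120.0 / cadence) * (1.0 + config.cycle_variability * rng.standard_normal())
        cycle = max(cycle, 0.4)
        stance = config.stance_fraction * cycle
        peak = config.vertical_peak + config.peak_per_kmh * (speed - config.reference_speed)
        start = int(round(t * rate))
        n_st = max(int(round(stance * rate)), 4)
        idx = np.arange(start, min(start + n_st, n))
        if idx.size:
            s = (idx - start) / n_st  # in [0, 1)
            fv[idx] = peak * _vertical_shape(s) * bw
            fml[idx] = config.ml_amplitude * np.sin(np.pi * s) * bw
            fap[idx] = -config.ap_amplitude * np.sin(2.0 * np.pi * s) * bw
            events.append(start)
        t += cycle
    grf = {"vertical": fv, "mediolateral": fml, "anteroposterior": fap}
    return grf, np.asarray(events, dtype=int)


def distribute_load(
    vertical: np.ndarray,
    events: np.ndarray,
    weights: SiteWeights | None = None,
) -> dict[str, np.ndarray]:
    """Split the total vertical force into four per-site traces.

    Within each stance the per-site share follows the phase-dependent
    weights (heel early, toe late); the four traces sum to the vertical
    force at every sample by construction.
    """
    weights = weights or SiteWeights()
    vertical = np.asarray(vertical, dtype=float)
    events = np.asarray(events, dtype=int)
    n = vertical.size
    phase = np.full(n, 0.5)
    for i, e in enumerate(events):
        end = events[i + 1] if i + 1 < events.size else n
        # stance = contiguous loaded span starting at the event
        j = e + 1
        while j < end and vertical[j] > 0:
            j += 1
        span = max(j - e, 1)
        k = np.arange(e, j)
        phase[k] = (k - e) / span
    shares = weights.shares(phase)
    return {s: shares[s] * vertical for s in SITES}


def sensor_forward(
    force: np.ndarray,
    params: SensorParams,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    circuit: MeasurementCircuit = MeasurementCircuit(),
    return_truth: bool = False,
):
    """Map a site force trace to a measured divider voltage trace.

    Static saturating law dR*(F) = -dr_max * F / (F + f_half); a first-
    order lag toward dR* produces rate-dependent hysteresis; the zero-load
    baseline creeps upward (charging); then divider voltage, Gaussian
    readout noise, and uniform mid-rise ADC quantization.
    """
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("site force must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / rate
    dr_target = -params.delta_r_max * force / (force + params.f_half)
    if params.lag_tau > 0:
        alpha = 1.0 - np.exp(-dt / params.lag_tau)
        # y[k] = (1-a) y[k-1] + a x[k], zero initial state
        dr = lfilter([alpha], [1.0, alpha - 1.0], dr_target)
    else:
        dr = dr_target
    t = np.arange(force.size) * dt
    baseline = params.r0 * (
        1.0 + (params.drift_magnitude / 100.0) * (1.0 - np.exp(-t / params.drift_tau))
    )
    resistance = baseline * (1.0 + dr / 100.0)
    v = resistance_to_voltage(resistance, circuit)
    if params.noise_sd > 0:
        v = v + params.noise_sd * rng.standard_normal(v.size)
    if params.adc_bits is not None:
        q = circuit.v_in / 2**params.adc_bits
        code = np.clip(np.floor(v / q), 0, 2**params.adc_bits - 1)
        v = (code + 0.5) * q
    v = np.clip(v, 0.0, np.nextafter(circuit.v_in, 0.0))
    if return_truth:
        return v, dr
    return v


def generate_trial(
    gait: GaitConfig | None = None,
    sensors: dict[str, SensorParams] | None = None,
    seed: int = 0,
    labels: dict[str, str] | None = None,
):
    """Generate one synchronized walking Trial plus its ground truth.

    Returns ``(trial, truth)`` where ``truth`` holds heel-strike indices,
    per-site forces, and the noiseless (pre-readout) percent resistance
    change of every sensor.
    """
    gait = gait or GaitConfig()
    sensors = sensors or default_sensor_params()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(1 + len(SITES))
    grf, events = generate_grf(gait, seed=seeds[0])
    site_forces = distribute_load(grf["vertical"], events)
    voltages = {}
    truth_dr = {}
    for i, s in enumerate(SITES):
        v, dr = sensor_forward(
            site_forces[s],
            sensors[s],
            rate=gait.sample_rate,
            seed=np.random.default_rng(seeds[1 + i]),
            return_truth=True,
        )
        voltages[s] = v
        truth_dr[s] = dr
    n = grf["vertical"].size
    trial = Trial(
        time=np.arange(n) / gait.sample_rate,
        voltages=voltages,
        grf=grf,
        body_mass=gait.body_mass,
        sample_rate=gait.sample_rate,
        labels=dict(labels or {}),
    )
    truth = {"events": events, "site_forces": site_forces, "delta_r": truth_dr}
    return trial, truth


def generate_session(
    days=(0, 1, 7),
    gait: GaitConfig | None = None,
    sensors: dict[str, SensorParams] | None = None,
    n_trials: int = 3,
    seed: int = 0,
):
    """Generate a multiday session: ``n_trials`` walking trials per day.

    Sensor parameters drift between days (f_half and r0 scale by
    (1 + day_drift_rate)^day), so models identified on day 0 degrade on
    later days.  Returns ``{day: [(trial, truth), ...]}``.
    """
    gait = gait or GaitConfig()
    sensors = sensors or default_sensor_params()
    out = {}
    for day in days:
        day_sensors = {s: p.drifted(day) for s, p in sensors.items()}
        trials = []
        for j in range(n_trials):
            trial_seed = np.random.SeedSequence([seed, int(day), j])
            trial, truth = generate_trial(
                gait,
                day_sensors,
                seed=trial_seed,
                labels={"day": str(day), "trial": str(j)},
            )
            trials.append((trial, truth))
        out[day] = trials
    return out


def generate_cyclic_test(
    params: SensorParams | None = None,
    n_cycles: int = 10_000,
    displacement_mm: float = 5.0,
    speed_mm_min: float = 800.0,
    k_inf: float = 100.0,  # N/mm, long-term stiffness
    k_relax: float = 40.0,  # N/mm, relaxing branch stiffness
    relax_tau: float = 8.0,  # s, viscoelastic relaxation time
    rate: float = 100.0,
    seed: int = 0,
):
    """Simulate a cyclic compression test of one sensor.

    Triangular displacement (0 -> displacement -> 0 at the given crosshead
    speed) drives a standard-linear-solid viscoelastic force map, whose
    peak force relaxes toward a steady state over the first cycles; the
    force then passes through the sensor model to a voltage trace.

    Returns a dict with displacement, force, delta_r (noiseless), voltage,
    and the samples-per-cycle period.
    """
    params = params or SensorParams(f_half=160.0)
    period_s = 2.0 * displacement_mm / (speed_mm_min / 60.0)
    per_cycle = int(round(period_s * rate))
    n = per_cycle * n_cycles
    t = np.arange(n) / rate
    tri = 1.0 - np.abs((t / period_s) % 1.0 - 0.5) * 2.0  # 0..1..0 per period, starts at 0
    x = displacement_mm * np.where(tri < 0, 0.0, tri)
    # standard linear solid: F = k_inf*x + k_relax*(x - x1), tau*dx1/dt = x - x1
    alpha = 1.0 - np.exp(-1.0 / (rate * relax_tau))
    x1 = lfilter([alpha], [1.0, alpha - 1.0], x)
    force = np.maximum(0.0, k_inf * x + k_relax * (x - x1))
    voltage, dr = sensor_forward(
        force, params, rate=rate, seed=seed, return_truth=True
    )
    return {
        "time": t,
        "displacement_mm": x,
        "force": force,
        "delta_r": dr,
        "voltage": voltage,
        "period_samples": per_cycle,
    }
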