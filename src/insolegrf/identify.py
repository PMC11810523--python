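"""Prediction-error identification of linear and Hammerstein-Wiener models.

Both model classes are fitted output-error style: coefficients minimize the
squared error of the *simulated* (free-run) response, not the one-step
prediction.  Orders are chosen by brute force over a pole/zero grid with
the same (n_b, n_f) applied to every input channel; the candidate with the
lowest validation scaled-RMS wins, with ties broken by fewer parameters
and then fewer poles.

Identifiability of the HW class is handled by normalizing every linear
block to unit static gain after fitting, so each input nonlinearity
carries its channel's gain; breakpoint abscissae are frozen at uniform
spacing over the 1st-99th percentile range of the identification data and
only ordinates are optimized, keeping the search reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .datasets import Dataset, concat_datasets, prepare_dataset, simulate_model
from .hw_model import (
    AXES,
    HWModel,
    LinearModel,
    PiecewiseLinear,
    TransferFunction,
    static_gain,
)
from .metrics import FitReport, r_squared, scaled_mae, scaled_rms
from .preprocess import STANDARD_GRAVITY, MeasurementCircuit

__all__ = [
    "OrderGrid",
    "SearchRecord",
    "IdentifyConfig",
    "ParticipantResult",
    "fit_linear",
    "fit_hw",
    "order_search",
    "identify_participant",
    "evaluate_model",
    "LINEAR_GRID",
    "HW_GRID",
]


@dataclass(frozen=True)
class OrderGrid:
    """Inclusive pole/zero ranges for the brute-force order search."""

    pole_range: tuple[int, int]
    zero_range: tuple[int, int]
    causal_only: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.pole_range, self.zero_range):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be non-empty with bounds >= 1")

    def candidates(self) -> list[tuple[int, int]]:
        """Admissible (n_b, n_f) pairs; causal means n_b <= n_f."""
        out = []
        for n_f in range(self.pole_range[0], self.pole_range[1] + 1):
            for n_b in range(self.zero_range[0], self.zero_range[1] + 1):
                if self.causal_only and n_b > n_f:
                    continue
                out.append((n_b, n_f))
        return out


#: Search ranges: linear models sweep all causal combinations up to ten
#: poles; the HW class is restricted to 1-8 poles and 1-5 zeros.
LINEAR_GRID = OrderGrid((1, 10), (1, 10))
HW_GRID = OrderGrid((1, 8), (1, 5))


@dataclass
class SearchRecord:
    """One attempted fit in a brute-force order search."""

    n_b: int
    n_f: int
    restart_seed: int
    converged: bool
    rms_id: float
    rms_val: float


# ---------------------------------------------------------------------------
# fast raw simulation and analytic-Jacobian helpers (arrays only)

def _pwl_weights(bp: np.ndarray, x: np.ndarray):
    """Segment index and (unclamped) barycentric weight for each sample.

    Leaving the weight unclamped outside the knot range reproduces the
    end-segment-slope extrapolation of :class:`PiecewiseLinear`.
    """
    j = np.clip(np.searchsorted(bp, x) - 1, 0, bp.size - 2)
    t = (x - bp[j]) / (bp[j + 1] - bp[j])
    return j, t


def _pwl_raw(bp: np.ndarray, vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    j, t = _pwl_weights(bp, x)
    return vals[j] * (1.0 - t) + vals[j + 1] * t


def _sim_linear_raw(theta: np.ndarray, U: list[np.ndarray], n_b: int, n_f: int) -> np.ndarray:
    stride = n_b + n_f
    y = 0.0
    for i, u in enumerate(U):
        b = theta[i * stride : i * stride + n_b]
        fc = theta[i * stride + n_b : (i + 1) * stride]
        y = y + lfilter(np.concatenate(([0.0], b)), np.concatenate(([1.0], fc)), u)
    return y


def _jac_linear_raw(theta: np.ndarray, U: list[np.ndarray], n_b: int, n_f: int) -> np.ndarray:
    """Analytic Jacobian of the MISO OE simulation w.r.t. all coefficients."""
    stride = n_b + n_f
    n = U[0].size
    J = np.zeros((n, theta.size))
    for i, u in enumerate(U):
        off = i * stride
        b = theta[off : off + n_b]
        f_poly = np.concatenate(([1.0], theta[off + n_b : off + stride]))
        # dy/db_j = q^-(1+j) [u / F];  dy/df_m = -q^-m [y_i / F]
        s = lfilter([1.0], f_poly, u)
        for jb in range(n_b):
            J[jb + 1 :, off + jb] = s[: n - jb - 1]
        if n_f:
            yi = lfilter(np.concatenate(([0.0], b)), f_poly, u)
            p = lfilter([1.0], f_poly, yi)
            for m in range(1, n_f + 1):
                J[m:, off + n_b + m - 1] = -p[: n - m]
    return J


def _sim_hw_raw(
    theta: np.ndarray,
    U: list[np.ndarray],
    bp_in: list[np.ndarray],
    bp_out: np.ndarray,
    n_b: int,
    n_f: int,
    nbp: int,
) -> np.ndarray:
    stride = nbp + n_b + n_f
    z = 0.0
    for i, u in enumerate(U):
        off = i * stride
        vals = theta[off : off + nbp]
        b = theta[off + nbp : off + nbp + n_b]
        fc = theta[off + nbp + n_b : off + stride]
        w = _pwl_raw(bp_in[i], vals, u)
        z = z + lfilter(np.concatenate(([0.0], b)), np.concatenate(([1.0], fc)), w)
    return _pwl_raw(bp_out, theta[-nbp:], z)


def _jac_hw_raw(
    theta: np.ndarray,
    U: list[np.ndarray],
    bp_in: list[np.ndarray],
    bp_out: np.ndarray,
    n_b: int,
    n_f: int,
    nbp: int,
) -> np.ndarray:
    """Analytic Jacobian of the HW simulation w.r.t. all free parameters.

    Input-PWL ordinates enter linearly before the filters (hat-basis
    columns filtered through G_i), filter coefficients as in the OE case,
    and the chain rule through the output map multiplies everything by the
    local slope h'(z); output ordinates contribute their hat basis directly.
    """
    stride = nbp + n_b + n_f
    n = U[0].size
    rows = np.arange(n)
    z = np.zeros(n)
    per = []
    for i, u in enumerate(U):
        off = i * stride
        vals = theta[off : off + nbp]
        b = theta[off + nbp : off + nbp + n_b]
        f_poly = np.concatenate(([1.0], theta[off + nbp + n_b : off + stride]))
        ji, ti = _pwl_weights(bp_in[i], u)
        w = vals[ji] * (1.0 - ti) + vals[ji + 1] * ti
        zi = lfilter(np.concatenate(([0.0], b)), f_poly, w)
        z += zi
        per.append((ji, ti, w, zi, f_poly, b))
    jo, to = _pwl_weights(bp_out, z)
    hvals = theta[-nbp:]
    dh = (hvals[jo + 1] - hvals[jo]) / (bp_out[jo + 1] - bp_out[jo])
    J = np.zeros((n, theta.size))
    for i, (ji, ti, w, zi, f_poly, b) in enumerate(per):
        off = i * stride
        phi = np.zeros((n, nbp))
        phi[rows, ji] = 1.0 - ti
        phi[rows, ji + 1] = ti
        J[:, off : off + nbp] = dh[:, None] * lfilter(
            np.concatenate(([0.0], b)), f_poly, phi, axis=0
        )
        s = lfilter([1.0], f_poly, w)
        for jb in range(n_b):
            J[jb + 1 :, off + nbp + jb] = dh[jb + 1 :] * s[: n - jb - 1]
        if n_f:
            p = lfilter([1.0], f_poly, zi)
            for m in range(1, n_f + 1):
                J[m:, off + nbp + n_b + m - 1] = -dh[m:] * p[: n - m]
    J[rows, theta.size - nbp + jo] = 1.0 - to
    J[rows, theta.size - nbp + jo + 1] = to
    return J


def _guard(resid: np.ndarray) -> np.ndarray:
    # unstable candidates blow up the free-run response; keep the residual
    # finite so the trust-region step can back off
    bad = ~np.isfinite(resid)
    if np.any(bad):
        resid = np.where(bad, 1e6, resid)
    return np.clip(resid, -1e8, 1e8)


def _stabilize(fc: np.ndarray) -> np.ndarray:
    """Radially shrink any denominator roots on/outside the unit circle."""
    if fc.size == 0:
        return fc
    poly = np.concatenate(([1.0], fc))
    roots = np.roots(poly)
    mags = np.abs(roots)
    if np.all(mags < 1.0):
        return fc
    roots = np.where(mags >= 1.0, roots / mags * 0.95, roots)
    return np.real(np.poly(roots))[1:]


def _arx_init(y: np.ndarray, U: list[np.ndarray], n_b: int, n_f: int):
    """Equation-error least squares for starting values (shared denominator)."""
    p = max(n_b, n_f)
    n = y.size
    if n <= p + len(U) * n_b + n_f:
        raise ValueError("dataset too short for the requested orders")
    cols = [-y[p - m : n - m] for m in range(1, n_f + 1)]
    for u in U:
        cols.extend(u[p - j : n - j] for j in range(1, n_b + 1))
    A = np.column_stack(cols)
    theta, *_ = np.linalg.lstsq(A, y[p:], rcond=None)
    fc = _stabilize(theta[:n_f])
    bs = theta[n_f:].reshape(len(U), n_b)
    return bs, fc


def _id_rms(dataset: Dataset, sim: np.ndarray, burn_in: int) -> float:
    return scaled_rms(dataset.output[burn_in:], sim[burn_in:], dataset.scale)


def _max_nfev(n_params: int, max_iter: int) -> int:
    # with analytic Jacobians each trust-region iteration costs ~1-3
    # residual evaluations, so this caps the outer-iteration count
    return max(3 * max_iter, 50)


def fit_linear(
    dataset: Dataset, n_b: int, n_f: int, max_iter: int = 200
) -> LinearModel:
    """Output-error fit of a MISO linear model with orders (n_b, n_f).

    Starts from an equation-error (ARX) least-squares solution and refines
    all numerator/denominator coefficients by damped least squares on the
    simulated response.  Warns (returning the best iterate) when the
    optimizer stops on its iteration budget rather than its tolerances.
    """
    channels = dataset.channels
    U = [dataset.inputs[c] for c in channels]
    y = dataset.output
    burn_in = max(n_b, n_f)
    bs, fc = _arx_init(y, U, n_b, n_f)
    theta0 = np.concatenate([np.concatenate([bs[i], fc]) for i in range(len(U))])

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            return _guard(_sim_linear_raw(theta, U, n_b, n_f)[burn_in:] - y[burn_in:])

    def jac(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            J = _jac_linear_raw(theta, U, n_b, n_f)[burn_in:]
            return np.nan_to_num(J, posinf=1e8, neginf=-1e8)

    sol = least_squares(
        resid,
        theta0,
        jac=jac,
        method="trf",
        ftol=1e-8,
        xtol=1e-10,
        gtol=1e-12,
        max_nfev=_max_nfev(theta0.size, max_iter),
    )
    if sol.status == 0:
        warnings.warn("fit_linear hit its iteration budget before converging", RuntimeWarning)
    stride = n_b + n_f
    linear = {}
    for i, c in enumerate(channels):
        b = sol.x[i * stride : i * stride + n_b]
        f = np.concatenate(([1.0], sol.x[i * stride + n_b : (i + 1) * stride]))
        linear[c] = TransferFunction(b, f)
    return LinearModel(axis=dataset.axis, channels=channels, linear=linear)


def _breakpoints(series: np.ndarray, n: int) -> np.ndarray:
    lo, hi = np.percentile(series, [1.0, 99.0])
    if hi <= lo:
        lo, hi = lo - 1.0, hi + 1.0
    return np.linspace(lo, hi, n)


def fit_hw(
    dataset: Dataset,
    n_b: int,
    n_f: int,
    n_breakpoints: int = 10,
    restarts: int = 2,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[HWModel, dict]:
    """Joint prediction-error fit of a MISO Hammerstein-Wiener model.

    Optimizes all input/output PWL ordinates and transfer-function
    coefficients on the simulated response.  Restart 1 starts from the
    linear fit wrapped in identity nonlinearities; further restarts
    perturb the PWL ordinates (N(0, 0.1 * range), seeded).  The restart
    with the lower identification RMS wins, and the returned model is
    canonicalized to unit static gain per linear block.
    """
    channels = dataset.channels
    U = [dataset.inputs[c] for c in channels]
    y = dataset.output
    burn_in = max(n_b, n_f)
    nbp = n_breakpoints
    rng = np.random.default_rng(seed)

    lin = fit_linear(dataset, n_b, n_f, max_iter=max_iter)
    bp_in = [_breakpoints(u, nbp) for u in U]
    # fold each branch gain into its input PWL so blocks start at unit gain
    parts = []
    for i, c in enumerate(channels):
        g = static_gain(lin.linear[c])
        if not np.isfinite(g) or abs(g) < 1e-12:
            g = 1.0
        parts.append(
            np.concatenate([g * bp_in[i], lin.linear[c].b / g, lin.linear[c].f[1:]])
        )
    z0 = simulate_model(lin, dataset)
    bp_out = _breakpoints(z0, nbp)
    theta0 = np.concatenate(parts + [bp_out.copy()])  # identity output map

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            sim = _sim_hw_raw(theta, U, bp_in, bp_out, n_b, n_f, nbp)
            return _guard(sim[burn_in:] - y[burn_in:])

    def jac(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            J = _jac_hw_raw(theta, U, bp_in, bp_out, n_b, n_f, nbp)[burn_in:]
            return np.nan_to_num(J, posinf=1e8, neginf=-1e8)

    stride = nbp + n_b + n_f
    best = None
    diag = {"restarts": []}
    for r in range(restarts):
        theta_r = theta0.copy()
        if r > 0:
            for i in range(len(U)):
                vals = theta_r[i * stride : i * stride + nbp]
                vals += rng.normal(0.0, 0.1 * np.ptp(vals), nbp)
            out_vals = theta_r[-nbp:]
            out_vals += rng.normal(0.0, 0.1 * np.ptp(out_vals), nbp)
        sol = least_squares(
            resid,
            theta_r,
            jac=jac,
            method="trf",
            ftol=1e-8,
            xtol=1e-10,
            gtol=1e-12,
            x_scale="jac",
            max_nfev=_max_nfev(theta_r.size, max_iter),
        )
        rms = _id_rms(dataset, _sim_hw_raw(sol.x, U, bp_in, bp_out, n_b, n_f, nbp), burn_in)
        diag["restarts"].append(
            {"restart": r, "rms_id": rms, "converged": sol.status != 0, "cost": float(sol.cost)}
        )
        if np.isfinite(rms) and (best is None or rms < best[1]):
            best = (sol.x, rms, sol.status != 0)
    if best is None:
        raise RuntimeError(f"all fit_hw restarts diverged for orders ({n_b}, {n_f})")
    theta, rms_id, converged = best
    diag.update(rms_id=rms_id, converged=converged)

    input_nl, linear = {}, {}
    for i, c in enumerate(channels):
        off = i * stride
        vals = theta[off : off + nbp].copy()
        b = theta[off + nbp : off + nbp + n_b].copy()
        fc = theta[off + nbp + n_b : off + stride]
        tf = TransferFunction(b, np.concatenate(([1.0], fc)))
        g = static_gain(tf)
        if np.isfinite(g) and abs(g) > 1e-12:
            tf = TransferFunction(b / g, tf.f)
            vals *= g
        input_nl[c] = PiecewiseLinear(bp_in[i], vals)
        linear[c] = tf
    model = HWModel(
        axis=dataset.axis,
        channels=channels,
        input_nl=input_nl,
        linear=linear,
        output_nl=PiecewiseLinear(bp_out, theta[-nbp:].copy()),
    )
    return model, diag


def _n_params(model) -> int:
    n = sum(g.n_b + g.n_f for g in model.linear.values())
    if isinstance(model, HWModel):
        n += sum(nl.values.size for nl in model.input_nl.values())
        n += model.output_nl.values.size
    return n


def order_search(
    dataset_id: Dataset,
    dataset_val: Dataset,
    grid: OrderGrid,
    model_class: str = "hw",
    seed: int = 0,
    n_breakpoints: int = 10,
    restarts: int = 2,
    max_iter: int = 200,
    eval_fn=None,
):
    """Brute-force order search; best model = lowest validation scaled-RMS.

    Fits every admissible (n_b, n_f) on the identification dataset, scores
    each candidate on the validation dataset (or with ``eval_fn(model)``,
    e.g. a segmented-gait evaluator), and returns the winner plus the full
    log.  Ties break toward fewer parameters, then fewer poles.
    """
    cands = grid.candidates()
    if not cands:
        raise ValueError("empty admissible order grid")
    log: list[SearchRecord] = []
    fits = []
    for n_b, n_f in cands:
        burn_in = max(n_b, n_f)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if model_class == "hw":
                    model, diag = fit_hw(
                        dataset_id, n_b, n_f,
                        n_breakpoints=n_breakpoints, restarts=restarts,
                        seed=seed, max_iter=max_iter,
                    )
                    converged = bool(diag["converged"])
                elif model_class == "linear":
                    model = fit_linear(dataset_id, n_b, n_f, max_iter=max_iter)
                    converged = True
                else:
                    raise ValueError(f"unknown model class {model_class!r}")
            rms_id = _id_rms(dataset_id, simulate_model(model, dataset_id), burn_in)
            if eval_fn is not None:
                rms_val = float(eval_fn(model))
            else:
                sim_val = simulate_model(model, dataset_val)
                rms_val = scaled_rms(
                    dataset_val.output[burn_in:], sim_val[burn_in:], dataset_val.scale
                )
            if not np.isfinite(rms_val):
                rms_val = np.inf
        except (ValueError, RuntimeError):
            log.append(SearchRecord(n_b, n_f, seed, False, np.inf, np.inf))
            continue
        log.append(SearchRecord(n_b, n_f, seed, converged, rms_id, rms_val))
        fits.append((model, log[-1]))
    if not fits:
        raise RuntimeError("every candidate fit failed in the order search")
    best_model, _ = min(
        fits, key=lambda mr: (mr[1].rms_val, _n_params(mr[0]), mr[1].n_f)
    )
    return best_model, log


@dataclass
class IdentifyConfig:
    """Study configuration: grids, breakpoints, restarts, seed, budget."""

    linear_grid: OrderGrid = LINEAR_GRID
    hw_grid: OrderGrid = HW_GRID
    n_breakpoints: int = 10
    restarts: int = 2
    seed: int = 0
    max_iter: int = 200
    axes: tuple[str, ...] = AXES
    selection: str = "time_series"  # or "segmented"
    circuit: MeasurementCircuit = field(default_factory=MeasurementCircuit)


@dataclass
class ParticipantResult:
    """Per-axis models, search logs and fit reports for one participant."""

    models: dict  # axis -> {"hw": HWModel, "linear": LinearModel}
    logs: dict  # axis -> {"hw": [SearchRecord], "linear": [SearchRecord]}
    reports: dict  # axis -> {"hw"|"linear": {"time_series"|"segmented": FitReport}}


def evaluate_model(model, dataset: Dataset, body_mass: float, burn_in: int | None = None) -> FitReport:
    """Time-series FitReport of a model on a prepared dataset (BW units)."""
    burn_in = model.burn_in if burn_in is None else burn_in
    y = dataset.output[burn_in:]
    yhat = simulate_model(model, dataset)[burn_in:]
    mg = body_mass * STANDARD_GRAVITY
    return FitReport(
        rms_pct=scaled_rms(y, yhat, dataset.scale),
        mae_pct=scaled_mae(y, yhat, dataset.scale),
        r_squared=r_squared(y, yhat),
        rms_abs=float(np.sqrt(np.mean((mg * (y - yhat)) ** 2))),
        mae_abs=float(np.mean(np.abs(mg * (y - yhat)))),
        n=int(y.size),
        axis=dataset.axis,
        evaluation_mode="time_series",
    )


def identify_participant(trials, config: IdentifyConfig | None = None) -> ParticipantResult:
    """Full per-participant study: identify on trials 1-2, validate on 3.

    Each trial is detrended independently (drift is trial-specific); the
    first two trials concatenate into the identification dataset and the
    third is held out.  Per axis, both model classes run their brute-force
    order search, and the winners are scored in both time-series and
    segmented-gait-cycle modes on the validation trial.
    """
    from .gait import segmented_fit_report  # local import: gait builds on datasets

    config = config or IdentifyConfig()
    if len(trials) < 3:
        raise ValueError("need at least three trials (two identification + one validation)")
    channels = trials[0].channels
    for t in trials[1:]:
        if t.channels != channels:
            raise ValueError("trials have mismatched channel sets")
    val_trial = trials[2]
    models, logs, reports = {}, {}, {}
    for axis in config.axes:
        ds_id = concat_datasets(
            [prepare_dataset(t, axis, "identification", config.circuit) for t in trials[:2]]
        )
        ds_val = prepare_dataset(val_trial, axis, "validation", config.circuit)
        eval_fn = None
        if config.selection == "segmented":
            eval_fn = lambda m: segmented_fit_report(val_trial, m, axis=axis).rms_pct
        models[axis], logs[axis], reports[axis] = {}, {}, {}
        for cls, grid in (("linear", config.linear_grid), ("hw", config.hw_grid)):
            model, log = order_search(
                ds_id,
                ds_val,
                grid,
                model_class=cls,
                seed=config.seed,
                n_breakpoints=config.n_breakpoints,
                restarts=config.restarts,
                max_iter=config.max_iter,
                eval_fn=eval_fn,
            )
            models[axis][cls] = model
            logs[axis][cls] = log
            reports[axis][cls] = {
                "time_series": evaluate_model(model, ds_val, val_trial.body_mass),
                "segmented": segmented_fit_report(val_trial, model, axis=axis),
            }
    return ParticipantResult(models=models, logs=logs, reports=reports)
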