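"""Output-error estimation, HW fitting, and the brute-force order search."""

import numpy as np
import pytest

from insolegrf import (
    Dataset,
    GaitConfig,
    HWModel,
    IdentifyConfig,
    LinearModel,
    OrderGrid,
    PiecewiseLinear,
    TransferFunction,
    evaluate_model,
    fit_hw,
    fit_linear,
    generate_trial,
    hw_simulate,
    identify_participant,
    order_search,
    simulate_model,
    tf_simulate,
)
from insolegrf.metrics import scaled_rms


def _oe_dataset(rng, n=500, role="identification"):
    """Noiseless data from a known 1-input OE model b=[1], f=[1,-0.5]."""
    u = rng.standard_normal(n)
    y = tf_simulate(TransferFunction([1.0], [1.0, -0.5]), u, check_stability=False)
    return Dataset({"HL": u}, y, scale=float(np.ptp(y)), axis="vertical", role=role)


class TestFitLinear:
    def test_noiseless_oe_recovery(self, rng):
        ds = _oe_dataset(rng)
        model = fit_linear(ds, 1, 1)
        held = _oe_dataset(np.random.default_rng(99), role="validation")
        sim = simulate_model(model, held)
        amp = np.abs(held.output).max()
        assert np.abs(held.output[1:] - sim[1:]).max() < 1e-6 * amp

    def test_fir_truth_recovered_exactly(self, rng):
        b_true = np.array([0.8, -0.3, 0.1])
        u = rng.standard_normal(600)
        y = tf_simulate(TransferFunction(b_true, [1.0]), u)
        ds = Dataset({"HL": u}, y, scale=float(np.ptp(y)))
        model = fit_linear(ds, 3, 0)
        np.testing.assert_allclose(model.linear["HL"].b, b_true, atol=1e-8)

    def test_independent_noise_gives_near_zero_r2(self):
        rng = np.random.default_rng(321)
        n = 2000
        inputs = {"HL": rng.standard_normal(n)}
        y = rng.standard_normal(n)  # unrelated to the input
        ds_id = Dataset(inputs, y, scale=float(np.ptp(y)))
        model = fit_linear(ds_id, 2, 2)
        y_val = rng.standard_normal(n)
        ds_val = Dataset({"HL": rng.standard_normal(n)}, y_val, scale=float(np.ptp(y_val)))
        rep = evaluate_model(model, ds_val, body_mass=80.0, burn_in=2)
        assert rep.r_squared <= 0.05

    def test_miso_channels_share_orders(self, rng):
        u = {c: rng.standard_normal(400) for c in ("TO", "HL")}
        y = (
            tf_simulate(TransferFunction([1.0], [1.0, -0.4]), u["TO"], check_stability=False)
            + tf_simulate(TransferFunction([0.5], [1.0, 0.2]), u["HL"], check_stability=False)
        )
        ds = Dataset(u, y, scale=float(np.ptp(y)))
        model = fit_linear(ds, 1, 1)
        assert model.linear["TO"].n_f == model.linear["HL"].n_f == 1
        sim = simulate_model(model, ds)
        assert scaled_rms(y[1:], sim[1:], ds.scale) < 1e-4


def _hammerstein_dataset(rng, n=1500, noise=0.0):
    """2-channel Hammerstein truth: saturating input maps, OE blocks."""
    u = {c: rng.standard_normal(n) for c in ("TO", "HL")}
    bp = np.linspace(-3, 3, 10)
    nls = {
        "TO": PiecewiseLinear(bp, 2.0 * np.tanh(bp)),
        "HL": PiecewiseLinear(bp, np.tanh(1.5 * bp)),
    }
    tfs = {
        "TO": TransferFunction([0.5], [1.0, -0.6]),
        "HL": TransferFunction([0.3], [1.0, -0.3]),
    }
    model = HWModel(
        axis="vertical",
        channels=("TO", "HL"),
        input_nl=nls,
        linear=tfs,
        output_nl=PiecewiseLinear.identity(np.linspace(-4, 4, 10)),
    )
    y = hw_simulate(model, u)
    if noise:
        y = y + noise * np.std(y) * rng.standard_normal(n)
    return Dataset(u, y, scale=float(np.ptp(y)), axis="vertical")


class TestFitHW:
    def test_nested_linear_truth(self, rng):
        ds = _oe_dataset(rng, n=800)
        lin = fit_linear(ds, 1, 1)
        hw, _ = fit_hw(ds, 1, 1, seed=0)
        val = _oe_dataset(np.random.default_rng(55), role="validation")
        rms_lin = scaled_rms(val.output[1:], simulate_model(lin, val)[1:], val.scale)
        rms_hw = scaled_rms(val.output[1:], simulate_model(hw, val)[1:], val.scale)
        assert rms_hw <= rms_lin + 1.0  # within 1 % RMS of the linear fit

    def test_hammerstein_recovery_noiseless(self):
        rng = np.random.default_rng(8)
        ds = _hammerstein_dataset(rng)
        model, diag = fit_hw(ds, 1, 1, seed=0)
        val = _hammerstein_dataset(np.random.default_rng(80))
        rms = scaled_rms(val.output[1:], simulate_model(model, val)[1:], val.scale)
        assert rms < 1.0

    def test_canonical_unit_static_gain(self):
        rng = np.random.default_rng(8)
        ds = _hammerstein_dataset(rng, n=800)
        model, _ = fit_hw(ds, 1, 1, seed=0)
        from insolegrf import static_gain

        for c in model.channels:
            assert static_gain(model.linear[c]) == pytest.approx(1.0, abs=1e-9)

    def test_constant_output_degenerate_scale(self):
        with pytest.raises(ValueError):
            Dataset({"HL": np.random.default_rng(0).standard_normal(100)},
                    np.zeros(100), scale=0.0)


class TestNormalizationInvariance:
    def test_gain_gauge_leaves_simulation_unchanged(self, rng):
        ds = _hammerstein_dataset(rng, n=300)
        bp = np.linspace(-3, 3, 10)
        model = HWModel(
            axis="vertical",
            channels=("TO", "HL"),
            input_nl={c: PiecewiseLinear(bp, np.tanh(bp)) for c in ("TO", "HL")},
            linear={c: TransferFunction([0.5], [1.0, -0.5]) for c in ("TO", "HL")},
            output_nl=PiecewiseLinear.identity(np.linspace(-4, 4, 10)),
        )
        y0 = hw_simulate(model, ds.inputs)
        c = 3.7
        rescaled = HWModel(
            axis="vertical",
            channels=model.channels,
            input_nl={
                ch: PiecewiseLinear(bp, c * np.tanh(bp)) for ch in model.channels
            },
            linear={
                ch: TransferFunction([0.5 / c], [1.0, -0.5]) for ch in model.channels
            },
            output_nl=model.output_nl,
        )
        np.testing.assert_allclose(hw_simulate(rescaled, ds.inputs), y0, atol=1e-12)


class TestOrderSearch:
    def test_singleton_grid(self, rng):
        ds_id = _oe_dataset(rng)
        ds_val = _oe_dataset(np.random.default_rng(1), role="validation")
        model, log = order_search(
            ds_id, ds_val, OrderGrid((1, 1), (1, 1)), model_class="linear"
        )
        assert len(log) == 1
        assert (model.orders()) == (1, 1)

    def test_true_order_in_grid_is_not_beaten(self, rng):
        u = rng.standard_normal(800)
        truth = TransferFunction([1.0, -0.2], [1.0, -0.9, 0.2])
        y = tf_simulate(truth, u, check_stability=False)
        ds_id = Dataset({"HL": u}, y, scale=float(np.ptp(y)))
        u2 = np.random.default_rng(7).standard_normal(800)
        y2 = tf_simulate(truth, u2, check_stability=False)
        ds_val = Dataset({"HL": u2}, y2, scale=float(np.ptp(y2)), role="validation")
        model, log = order_search(
            ds_id, ds_val, OrderGrid((1, 3), (1, 2)), model_class="linear"
        )
        true_rec = next(r for r in log if (r.n_b, r.n_f) == (2, 2))
        best_rec = min(log, key=lambda r: r.rms_val)
        assert best_rec.rms_val <= true_rec.rms_val + 1e-6

    def test_selected_is_log_minimum(self, rng):
        ds_id = _oe_dataset(rng)
        ds_val = _oe_dataset(np.random.default_rng(3), role="validation")
        model, log = order_search(
            ds_id, ds_val, OrderGrid((1, 2), (1, 2)), model_class="linear"
        )
        best = min(r.rms_val for r in log)
        sim = simulate_model(model, ds_val)
        b = max(model.orders())
        assert scaled_rms(ds_val.output[b:], sim[b:], ds_val.scale) == pytest.approx(
            best, rel=1e-9
        )

    def test_exact_tie_breaks_to_fewer_parameters(self, rng):
        ds_id = _oe_dataset(rng)
        ds_val = _oe_dataset(np.random.default_rng(3), role="validation")
        # constant evaluator ties every candidate exactly
        model, log = order_search(
            ds_id, ds_val, OrderGrid((1, 3), (1, 2)), model_class="linear",
            eval_fn=lambda m: 5.0,
        )
        assert model.orders() == (1, 1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            OrderGrid((2, 1), (1, 1))


class TestIdentifyParticipant:
    def test_mismatched_channels_rejected(self, short_trial):
        trial, _ = short_trial
        broken = type(trial)(
            time=trial.time,
            voltages={"TO": trial.voltages["TO"]},
            grf=trial.grf,
            body_mass=trial.body_mass,
            sample_rate=trial.sample_rate,
        )
        with pytest.raises(ValueError, match="mismatch"):
            identify_participant([trial, trial, broken])

    def test_needs_three_trials(self, short_trial):
        with pytest.raises(ValueError, match="three"):
            identify_participant([short_trial[0]])

    def test_small_study_structure(self, short_gait_config):
        trials = [generate_trial(short_gait_config, seed=s)[0] for s in (20, 21, 22)]
        cfg = IdentifyConfig(
            linear_grid=OrderGrid((2, 2), (2, 2)),
            hw_grid=OrderGrid((2, 2), (2, 2)),
            axes=("vertical",),
            max_iter=40,
        )
        result = identify_participant(trials, cfg)
        assert set(result.models) == {"vertical"}
        assert isinstance(result.models["vertical"]["hw"], HWModel)
        assert isinstance(result.models["vertical"]["linear"], LinearModel)
        for cls in ("hw", "linear"):
            rep = result.reports["vertical"][cls]
            assert rep["time_series"].rms_pct > 0
            assert rep["segmented"].evaluation_mode == "segmented"
        # a sane fit on synthetic data explains most of the variance
        assert result.reports["vertical"]["hw"]["time_series"].r_squared > 0.9
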