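"""Residuals and first/second-order residual sensitivities."""

import numpy as np
import pytest

import rncfit as rf
from rncfit.models import (
    Dataset,
    LogScaleModel,
    ParameterVector,
    first_order_sensitivities,
    residuals,
    second_order_sensitivities,
    sensitivity_bundle,
)


def single_datum(y=1.0, t=1.0, sigma=1.0):
    return Dataset.from_arrays([t], [y], sigma)


class TestParameterVector:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector([1.0, 2.0], ["a"])

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParameterVector([-1.0], ["a"], [[0.0, np.inf]])


class TestDataset:
    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            Dataset.from_arrays([1.0], [1.0], 0.0)

    def test_csv_round_trip(self, tmp_path):
        ds = Dataset.from_arrays([1.0, 2.0], [0.5, 0.2], 0.1, condition="c0", observable="P")
        path = tmp_path / "d.csv"
        ds.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.frame.equals(ds.frame)

    def test_condition_defaults_to_single(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("time,value,sigma\n1.0,1.0,1.0\n")
        ds = Dataset.from_csv(path)
        assert list(ds.frame["condition"]) == [""]


class TestResiduals:
    def test_model1_optimum_residual_is_zero(self, model1, model1_data):
        assert residuals(model1, [0.0], model1_data) == pytest.approx([0.0])

    def test_model1_half_life(self, model1, model1_data):
        # r = 1 - e^{-log 2} = 0.5
        assert residuals(model1, [np.log(2.0)], model1_data) == pytest.approx([0.5])

    def test_perfect_fit_gives_zero_vector(self):
        model = rf.builtin_model("exp_decay")
        t = np.array([0.5, 1.0, 2.0])
        theta = np.array([0.7, 1.3])
        y = model.predictions(theta, Dataset.from_arrays(t, np.zeros(3), 1.0))
        ds = Dataset.from_arrays(t, y, 0.3)
        assert np.allclose(residuals(model, theta, ds), 0.0)

    def test_sum_of_squares_matches_objective(self, model2_fit):
        model, ds, res, _ = model2_fit
        theta = np.array([0.8, 1.1])
        r = residuals(model, theta, ds)
        obj = rf.chi2_objective(model, ds)
        assert obj.evaluate(theta) == pytest.approx(float(r @ r), rel=1e-12)


class TestFirstOrderSensitivities:
    def test_model1_at_zero(self, model1, model1_data):
        J = first_order_sensitivities(model1, [0.0], model1_data)
        assert J == pytest.approx(np.array([[1.0]]))

    def test_linear_model_jacobian_constant(self, linear2_model, linear2_data):
        J1 = first_order_sensitivities(linear2_model, [0.0, 0.0], linear2_data)
        J2 = first_order_sensitivities(linear2_model, [5.0, -3.0], linear2_data)
        assert np.allclose(J1, J2)

    def test_sensitivity_equations_match_finite_differences(self):
        design, ds = rf.fixture("model3_default")
        model = rf.model_for(design)
        theta = rf.theta_true_vector(design, model)
        J = first_order_sensitivities(model, theta, ds)
        Jfd = np.empty_like(J)
        for k in range(theta.N):
            h = 1e-6 * max(abs(theta.values[k]), 1.0)
            up, dn = theta.values.copy(), theta.values.copy()
            up[k] += h
            dn[k] -= h
            Jfd[:, k] = (residuals(model, up, ds) - residuals(model, dn, ds)) / (2 * h)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(J)) < 1e-4


class TestSecondOrderSensitivities:
    def test_model1_at_zero(self, model1, model1_data):
        H = second_order_sensitivities(model1, [0.0], model1_data)
        assert H == pytest.approx(np.array([[[-1.0]]]))

    def test_linear_model_analytic_and_fd_vanish(self, linear2_model, linear2_data):
        theta = linear2_model.parameter_vector([1.0, -0.5])
        H = second_order_sensitivities(linear2_model, theta, linear2_data)
        assert np.all(H == 0.0)
        Hfd = second_order_sensitivities(
            linear2_model, theta, linear2_data, force_finite_differences=True
        )
        assert np.max(np.abs(Hfd)) < 1e-6

    def test_power_model_second_derivative(self):
        model = rf.builtin_model("power", n=3)
        ds = single_datum(y=5.0)
        H = second_order_sensitivities(model, [1.0], ds)
        assert H == pytest.approx(np.array([[[-6.0]]]))

    @pytest.mark.parametrize("name", ["exp_fixed", "exp_decay", "reciprocal", "power"])
    def test_finite_differences_match_analytic(self, name):
        model = rf.builtin_model(name)
        ds = Dataset.from_arrays([0.5, 1.0, 2.0], [1.0, 0.7, 0.4], 0.5)
        grid = {
            "exp_fixed": [[-1.0], [0.3], [2.0]],
            "exp_decay": [[0.3, 0.5], [1.0, 2.0]],
            "reciprocal": [[0.5], [1.0], [3.0]],
            "power": [[0.7], [1.0], [2.0]],
        }[name]
        for theta in grid:
            Ha = second_order_sensitivities(model, np.array(theta), ds)
            Hf = second_order_sensitivities(
                model, np.array(theta), ds, force_finite_differences=True
            )
            assert np.max(np.abs(Ha - Hf)) <= 1e-5 * max(np.max(np.abs(Ha)), 1e-3)

    def test_step_near_bound_rejected(self):
        model = rf.builtin_model("exp_decay")
        theta = model.parameter_vector([1.0, 1e-6])  # A0 within step of lower bound 0
        ds = single_datum()
        with pytest.raises(ValueError, match="smaller step|one-sided"):
            second_order_sensitivities(model, theta, ds, force_finite_differences=True)

    def test_symmetry_exact_after_construction(self, model2_fit):
        model, ds, res, _ = model2_fit
        H = second_order_sensitivities(
            model, res.theta_hat, ds, force_finite_differences=True
        )
        assert np.max(np.abs(H - np.swapaxes(H, 1, 2))) == 0.0


class TestBuiltinModels:
    def test_exp_fixed_at_zero_rate(self, model1):
        assert model1.predict(1.0, [0.0]) == pytest.approx(1.0)

    def test_exp_decay_half_life(self):
        model = rf.builtin_model("exp_decay")
        assert model.predict(1.0, [np.log(2.0), 2.0]) == pytest.approx(1.0)

    def test_enzyme_without_product_formation(self):
        model = rf.builtin_model("enzyme", conditions={"": {"E0": 0.5}})
        P = model.predict(np.array([1.0, 5.0, 20.0]), [10.0, 10.0, 0.0, 1.0], observable="P")
        assert np.allclose(P, 0.0, atol=1e-9)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown built-in"):
            rf.builtin_model("nope")

    def test_even_power_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            rf.builtin_model("power", n=2)


class TestResidualSignConvention:
    def test_geometry_invariant_under_residual_negation(self, model2_fit):
        """Negating the residual convention flips J and H but leaves the
        metric and the Christoffel symbols unchanged (both are bilinear in
        the sensitivities)."""
        model, ds, res, _ = model2_fit
        b = sensitivity_bundle(model, res.theta_hat, ds)
        m1 = rf.metric_from_jacobian(b.J)
        m2 = rf.metric_from_jacobian(-b.J)
        assert np.allclose(m1.g, m2.g)
        g1 = rf.christoffel_symbols(b.J, b.H, m1.g_inv).Gamma
        g2 = rf.christoffel_symbols(-b.J, -b.H, m2.g_inv).Gamma
        assert np.allclose(g1, g2)


class TestLogScale:
    def test_log_chart_jacobian_chain_rule(self):
        base = rf.builtin_model("exp_decay")
        logm = LogScaleModel(base)
        ds = Dataset.from_arrays([1.0, 2.0], [0.5, 0.2], 0.1)
        u = np.log(np.array([0.7, 1.2]))
        J_log = first_order_sensitivities(logm, u, ds)
        J_nat = first_order_sensitivities(base, np.exp(u), ds)
        assert np.allclose(J_log, J_nat * np.exp(u)[None, :])

    def test_log_chart_hessian_matches_finite_differences(self):
        base = rf.builtin_model("exp_decay")
        logm = LogScaleModel(base)
        ds = Dataset.from_arrays([1.0, 2.0], [0.5, 0.2], 0.1)
        u = logm.parameter_vector(np.log([0.7, 1.2]))
        Ha = second_order_sensitivities(logm, u, ds)
        Hf = second_order_sensitivities(logm, u, ds, force_finite_differences=True)
        assert np.max(np.abs(Ha - Hf)) < 1e-5
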