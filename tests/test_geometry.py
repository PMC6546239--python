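"""Metric, Christoffel symbols, geodesics, RNC map, and the surrogate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rncfit as rf
from rncfit.geometry import BVPError, SingularMetricError
from rncfit.models import Dataset, sensitivity_bundle


class TestMetric:
    def test_model1_unit_metric(self, model1_snapshot):
        assert model1_snapshot.metric.g == pytest.approx(np.array([[1.0]]))

    def test_two_identical_data_points(self):
        m = rf.metric_from_jacobian(np.array([[1.0], [1.0]]))
        assert m.g == pytest.approx(np.array([[2.0]]))
        assert m.g_inv == pytest.approx(np.array([[0.5]]))

    def test_zero_jacobian_raises_singular(self):
        with pytest.raises(SingularMetricError, match="singular metric"):
            rf.metric_from_jacobian(np.zeros((3, 2)))

    def test_rank_deficient_jacobian_names_null_direction(self):
        # two redundant amplitude parameters: J columns proportional
        J = np.array([[1.0, 2.0], [0.5, 1.0], [2.0, 4.0]])
        with pytest.raises(SingularMetricError) as exc:
            rf.metric_from_jacobian(J)
        d = exc.value.null_direction
        assert abs(d @ np.array([2.0, -1.0]) / np.linalg.norm([2.0, -1.0])) == pytest.approx(
            1.0, abs=1e-8
        )


class TestChristoffel:
    @pytest.mark.parametrize("k1", [-1.0, 0.0, 0.7, 2.0])
    def test_model1_constant_gamma(self, model1, model1_data, k1):
        """Gamma^1_11 = -1 for the one-parameter exponential, at any k1."""
        b = sensitivity_bundle(model1, model1.parameter_vector([k1]), model1_data)
        m = rf.metric_from_jacobian(b.J)
        gamma = rf.christoffel_symbols(b.J, b.H, m.g_inv)
        assert gamma.Gamma == pytest.approx(np.array([[[-1.0]]]), abs=1e-10)

    def test_linear_model_flat(self, linear2_snapshot):
        assert np.allclose(linear2_snapshot.christoffel.Gamma, 0.0)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.0, 4.0])
    def test_reciprocal_gamma_minus_two_over_theta(self, theta):
        model = rf.builtin_model("reciprocal")
        ds = Dataset.from_arrays([1.0], [3.0], 1.0)
        b = sensitivity_bundle(model, model.parameter_vector([theta]), ds)
        m = rf.metric_from_jacobian(b.J)
        gamma = rf.christoffel_symbols(b.J, b.H, m.g_inv)
        assert gamma.Gamma[0, 0, 0] == pytest.approx(-2.0 / theta, rel=1e-8)

    def test_symmetry_in_lower_indices(self, model2_fit):
        _, _, _, snap = model2_fit
        G = snap.christoffel.Gamma
        assert np.max(np.abs(G - np.swapaxes(G, 1, 2))) == 0.0


class TestGeodesicShoot:
    def test_zero_velocity_stays_at_optimum(self, model1_snapshot):
        sol = rf.geodesic_shoot(model1_snapshot, [0.0], t_eval=np.linspace(0, 1, 5))
        assert np.allclose(sol.theta_path, 0.0)
        assert not sol.diverged

    def test_model1_matches_closed_form(self, model1_snapshot):
        taus = np.linspace(0.1, 1.0, 7)
        sol = rf.geodesic_shoot(model1_snapshot, [0.5], t_eval=taus)
        expected = [rf.model1_closed_form(0.5, t) for t in taus]
        assert sol.theta_path[:, 0] == pytest.approx(expected, abs=1e-8)

    def test_finite_time_blow_up(self, model1_snapshot):
        sol = rf.geodesic_shoot(model1_snapshot, [1.5])
        assert sol.diverged
        assert sol.tau_star == pytest.approx(2.0 / 3.0, abs=1e-4)


class TestRNCMap:
    def test_optimum_maps_to_origin(self, model1_snapshot):
        p = rf.rnc_map(model1_snapshot, [0.0])
        assert p.v == pytest.approx([0.0], abs=1e-8)
        assert p.s2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k1", [-2.0, -1.0, 0.5, 1.0, 3.0, 5.0])
    def test_model1_oracle_equivalence(self, model1_snapshot, k1):
        """Numerical BVP matches the closed form v = 1 - exp(-k1)."""
        v = rf.rnc_map(model1_snapshot, [k1]).v[0]
        assert abs(v - (1.0 - math.exp(-k1))) < 1e-6

    def test_linear_model_identity_shift(self, linear2_snapshot):
        theta_star = linear2_snapshot.theta_hat.values + np.array([3.0, -2.0])
        v = rf.rnc_map(linear2_snapshot, theta_star).v
        assert v == pytest.approx(theta_star - linear2_snapshot.theta_hat.values, abs=1e-8)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(-3.0, 0.9))
    def test_round_trip_on_model1(self, model1_snapshot, v):
        """rnc_map inverts geodesic_shoot wherever the geodesic survives."""
        sol = rf.geodesic_shoot(model1_snapshot, [v])
        assert not sol.diverged
        back = rf.rnc_map(model1_snapshot, sol.theta_end).v[0]
        assert abs(back - v) < 1e-6

    def test_round_trip_on_curved_two_parameter_model(self, model2_fit):
        _, _, _, snap = model2_fit
        rng = np.random.default_rng(7)
        for _ in range(5):
            v = rng.normal(0, 0.3, size=2)
            sol = rf.geodesic_shoot(snap, v)
            if sol.diverged:
                continue
            back = rf.rnc_map(snap, sol.theta_end).v
            assert np.linalg.norm(back - v) < 1e-6

    def test_unreachable_point_raises_with_hint(self, model1_snapshot):
        # k1 so large that the required velocity exceeds any representable one
        with pytest.raises(BVPError, match="boundary"):
            rf.rnc_map(model1_snapshot, [200.0])


class TestSurrogate:
    def test_value_at_optimum(self, model1_snapshot):
        assert rf.surrogate_chi2(model1_snapshot, [0.0]) == pytest.approx(
            model1_snapshot.chi2_hat, abs=1e-12
        )

    @pytest.mark.parametrize("k1", [-2.0, -0.5, 0.5, 1.0, 3.0])
    def test_exact_for_model1(self, model1_snapshot, k1):
        """chi2_tilde equals (1 - e^{-k1})^2: the manifold is flat, so the
        surrogate reproduces the original objective exactly."""
        val = rf.surrogate_chi2(model1_snapshot, [k1])
        assert abs(val - (1.0 - math.exp(-k1)) ** 2) < 1e-8

    def test_exact_for_linear_models(self, linear2_model, linear2_data, linear2_snapshot):
        obj = rf.chi2_objective(linear2_model, linear2_data)
        for theta in ([0.0, 0.0], [2.0, -1.0], [-3.0, 4.0]):
            assert rf.surrogate_chi2(linear2_snapshot, theta) == pytest.approx(
                obj.evaluate(np.array(theta)), abs=1e-8
            )

    def test_quadratic_form_consistency(self, model2_fit):
        """chi2_tilde - chi2_hat equals the squared arc length s2 = v^T g v."""
        _, _, _, snap = model2_fit
        theta = snap.theta_hat.values + np.array([0.2, -0.1])
        p = rf.rnc_map(snap, theta)
        assert rf.surrogate_chi2(snap, theta) - snap.chi2_hat == pytest.approx(p.s2, rel=1e-10)

    def test_vanishing_christoffel_embedding(self, model2_fit):
        """Zeroing Gamma reduces the surrogate to the Fisher-information
        quadratic form chi2_hat + (theta - theta_hat)^T g (theta - theta_hat)."""
        _, _, _, snap = model2_fit
        flat = rf.GeometrySnapshot(
            theta_hat=snap.theta_hat,
            chi2_hat=snap.chi2_hat,
            metric=snap.metric,
            christoffel=rf.ChristoffelTensor(np.zeros_like(snap.christoffel.Gamma)),
        )
        delta = np.array([0.3, -0.2])
        theta = snap.theta_hat.values + delta
        expected = snap.chi2_hat + delta @ snap.metric.g @ delta
        assert rf.surrogate_chi2(flat, theta) == pytest.approx(expected, abs=1e-8)

    def test_local_agreement_beats_quadratic_order(self):
        """|chi2_tilde - chi2| = o(||theta - theta_hat||^2) near an optimum
        with vanishing residuals.

        (With nonzero residuals at the optimum the two objectives differ at
        second order by the extrinsic-curvature term 2 r_hat . H, which the
        constant-Christoffel construction deliberately neglects; on
        noise-free data that term vanishes and the surrogate is third-order
        accurate.)"""
        from rncfit.simulate import SimulationDesign, model_for, simulate

        design = SimulationDesign(
            model_name="exp_decay",
            theta_true={"k1": 1.0, "A0": 1.0},
            times=[1.0, 2.0, 3.0],
            sigma=0.02,
            seed=0,
            apply_noise=False,
        )
        ds = simulate(design)
        model = model_for(design)
        obj = rf.chi2_objective(model, ds)
        res = rf.fit(obj, model.parameter_vector([0.5, 0.5]), n_restarts=2, seed=0)
        snap = rf.compute_geometry(model, res.theta_hat, ds)
        direction = np.array([1.0, 0.5])
        ratios = []
        for h in (0.3, 0.03):
            theta = snap.theta_hat.values + h * direction
            err = abs(rf.surrogate_chi2(snap, theta) - obj.evaluate(theta))
            ratios.append(err / h**2)
        assert ratios[1] < 0.3 * ratios[0]

    def test_gradient_zero_and_hessian_2g_at_optimum(self, model2_fit):
        _, _, _, snap = model2_fit
        grad, hess = rf.surrogate_gradient_hessian(snap, snap.theta_hat.values)
        assert np.linalg.norm(grad) < 1e-6 * max(1.0, np.linalg.norm(2 * snap.metric.g))
        assert hess == pytest.approx(2.0 * snap.metric.g, rel=1e-4)

    def test_linear_model_hessian_2g_everywhere(self, linear2_snapshot):
        theta = linear2_snapshot.theta_hat.values + np.array([2.0, -1.0])
        _, hess = rf.surrogate_gradient_hessian(linear2_snapshot, theta)
        assert hess == pytest.approx(2.0 * linear2_snapshot.metric.g, rel=1e-6)


class TestModel1ClosedForm:
    def test_zero_velocity(self):
        assert rf.model1_closed_form(0.0, 0.7) == 0.0

    def test_inverse_of_unit_point(self):
        v = 1.0 - math.exp(-1.0)
        assert rf.model1_closed_form(v, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_domain_error_at_boundary(self):
        with pytest.raises(ValueError, match="boundary"):
            rf.model1_closed_form(1.0, 1.0)

    def test_divergence_approaching_boundary(self):
        assert rf.model1_closed_form(1.0 - 1e-12, 1.0) > 25.0


class TestBoundaryScan:
    def test_model1_bounded_direction(self, model1_snapshot):
        assert rf.boundary_scan(model1_snapshot, [1.0]) == pytest.approx(1.0, abs=1e-6)

    def test_model1_unbounded_direction(self, model1_snapshot):
        assert rf.boundary_scan(model1_snapshot, [-1.0], v_max=1e4) == math.inf

    def test_linear_model_unbounded_everywhere(self, linear2_snapshot):
        for d in ([1.0, 0.0], [0.0, 1.0], [1.0, -1.0]):
            assert rf.boundary_scan(linear2_snapshot, d, v_max=100.0) == math.inf


class TestSnapshotSerialization:
    def test_json_round_trip(self, model2_fit, tmp_path):
        _, _, _, snap = model2_fit
        path = tmp_path / "snap.json"
        snap.save(path)
        back = rf.GeometrySnapshot.load(path)
        assert np.allclose(back.metric.g, snap.metric.g)
        assert np.allclose(back.christoffel.Gamma, snap.christoffel.Gamma)
        assert np.allclose(back.theta_hat.values, snap.theta_hat.values)
        assert back.parameter_scale == snap.parameter_scale
        # reusable without the model: surrogate evaluates identically
        theta = snap.theta_hat.values * 1.1 + 0.05
        assert rf.surrogate_chi2(back, theta) == pytest.approx(
            rf.surrogate_chi2(snap, theta), rel=1e-9
        )
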