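"""Local Riemannian geometry of the model manifold at the optimum.

The residual map r(theta) embeds the N-dimensional parameter space into the
M-dimensional data space; the pullback of the Euclidean data-space metric is

    g_{mu nu} = sum_m (dr_m/dtheta_mu)(dr_m/dtheta_nu),

the Fisher information for Gaussian noise.  The connection coefficients

    Gamma^mu_{ab} = g^{mu nu} sum_m (dr_m/dtheta_nu)(d2 r_m/dtheta_a dtheta_b)

are frozen at the optimum theta_hat and inserted into the otherwise exact
geodesic equation.  Initial velocities of geodesics from theta_hat are
Riemann normal coordinates (RNC) v; the surrogate objective

    chi2_tilde(theta) = chi2(theta_hat) + v(theta)^T g_hat v(theta)

is quadratic in v but — because solutions of the quadratic geodesic ODE can
blow up in finite time — bounded along directions in which the model
manifold has a boundary.  Finite-time blow-up of a geodesic is therefore a
meaningful outcome, not an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp

from .models import Dataset, ModelSpec, ParameterVector, sensitivity_bundle


class SingularMetricError(RuntimeError):
    """The pullback metric is (numerically) singular: the parameterization is
    structurally non-identifiable and must be reduced before the geometric
    analysis applies."""

    def __init__(self, message: str, null_direction: np.ndarray | None = None):
        super().__init__(message)
        self.null_direction = null_direction


class BVPError(RuntimeError):
    """The geodesic boundary value problem did not converge.  The target
    point may lie beyond the boundary of the approximated model manifold."""

    def __init__(self, message: str, best_residual: float = math.inf):
        super().__init__(message)
        self.best_residual = best_residual


# ---------------------------------------------------------------------------
# tensors at the optimum


@dataclass
class MetricTensor:
    g: np.ndarray
    g_inv: np.ndarray
    condition_number: float


@dataclass
class ChristoffelTensor:
    Gamma: np.ndarray  # (N, N, N), symmetric in the last two indices


def metric_from_jacobian(J: np.ndarray, cond_max: float = 1e12) -> MetricTensor:
    """Pullback metric g = J^T J with inverse and condition number.

    Raises :class:`SingularMetricError` (naming the approximate null-space
    direction) when the metric cannot be inverted reliably.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    g = J.T @ J
    w, V = np.linalg.eigh(g)
    if w[-1] <= 0 or w[0] <= 0 or (w[-1] / w[0]) > cond_max:
        cond = math.inf if w[0] <= 0 else w[-1] / w[0]
        raise SingularMetricError(
            "the model manifold has a singular metric (condition number "
            f"{cond:.3g}), indicating structural non-identifiability along "
            f"direction {np.round(V[:, 0], 6).tolist()}",
            null_direction=V[:, 0],
        )
    g_inv = (V / w) @ V.T
    return MetricTensor(g=g, g_inv=g_inv, condition_number=float(w[-1] / w[0]))


def christoffel_symbols(
    J: np.ndarray, H: np.ndarray, g_inv: np.ndarray
) -> ChristoffelTensor:
    """Christoffel symbols of the second kind from residual sensitivities:
    Gamma^mu_{ab} = g^{mu nu} sum_m J[m, nu] H[m, a, b]."""
    Gamma = np.einsum("un,mn,mab->uab", g_inv, np.atleast_2d(J), H)
    Gamma = 0.5 * (Gamma + np.swapaxes(Gamma, 1, 2))
    return ChristoffelTensor(Gamma=Gamma)


@dataclass
class GeometrySnapshot:
    """Everything frozen at the optimum: theta_hat, chi2_hat, metric, and
    the (constant) Christoffel tensor, plus the chart and the numerical
    settings used downstream."""

    theta_hat: ParameterVector
    chi2_hat: float
    metric: MetricTensor
    christoffel: ChristoffelTensor
    parameter_scale: str = "natural"
    theta_bound: float = 1e6
    xi_bound: float = 1e12
    rtol: float = 1e-10
    atol: float = 1e-12
    bvp_tol: float = 1e-8

    @property
    def N(self) -> int:
        return self.theta_hat.N

    def to_dict(self) -> dict:
        return {
            "parameter_names": self.theta_hat.names,
            "theta_hat": self.theta_hat.values.tolist(),
            "bounds": self.theta_hat.bounds.tolist(),
            "chi2_hat": self.chi2_hat,
            "g": self.metric.g.tolist(),
            "g_inv": self.metric.g_inv.tolist(),
            "condition_number": self.metric.condition_number,
            "Gamma": self.christoffel.Gamma.tolist(),
            "parameter_scale": self.parameter_scale,
            "tolerances": {
                "theta_bound": self.theta_bound,
                "xi_bound": self.xi_bound,
                "rtol": self.rtol,
                "atol": self.atol,
                "bvp_tol": self.bvp_tol,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeometrySnapshot":
        tols = d.get("tolerances", {})
        return cls(
            theta_hat=ParameterVector(
                np.asarray(d["theta_hat"], float), d["parameter_names"], np.asarray(d["bounds"])
            ),
            chi2_hat=float(d["chi2_hat"]),
            metric=MetricTensor(
                g=np.asarray(d["g"], float),
                g_inv=np.asarray(d["g_inv"], float),
                condition_number=float(d["condition_number"]),
            ),
            christoffel=ChristoffelTensor(Gamma=np.asarray(d["Gamma"], float)),
            parameter_scale=d.get("parameter_scale", "natural"),
            **{k: float(tols[k]) for k in tols},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "GeometrySnapshot":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compute_geometry(
    model: ModelSpec,
    theta_hat: ParameterVector,
    data: Dataset,
    fd_step: float = 1e-4,
    parameter_scale: str = "natural",
    **snapshot_kwargs,
) -> GeometrySnapshot:
    """Evaluate residual sensitivities at theta_hat and assemble the frozen
    geometry (chi2_hat, metric, Christoffel symbols)."""
    bundle = sensitivity_bundle(model, theta_hat, data, step=fd_step)
    metric = metric_from_jacobian(bundle.J)
    gamma = christoffel_symbols(bundle.J, bundle.H, metric.g_inv)
    chi2_hat = float(np.sum(bundle.r**2))
    return GeometrySnapshot(
        theta_hat=theta_hat,
        chi2_hat=chi2_hat,
        metric=metric,
        christoffel=gamma,
        parameter_scale=parameter_scale,
        **snapshot_kwargs,
    )


# ---------------------------------------------------------------------------
# geodesics of the frozen connection


@dataclass
class GeodesicSolution:
    """theta(tau) and xi(tau) = theta_dot(tau) on tau in [0, 1] (or up to the
    escape time tau_star when the solution blows up in finite tau)."""

    tau_grid: np.ndarray
    theta_path: np.ndarray  # (n_tau, N)
    velocity_path: np.ndarray  # (n_tau, N)
    initial_velocity: np.ndarray
    diverged: bool
    tau_star: float | None = None

    @property
    def theta_end(self) -> np.ndarray:
        return self.theta_path[-1]


@dataclass
class RNCPoint:
    """Riemann normal coordinates v of a parameter point, with squared arc
    length s2 = v^T g_hat v (the surrogate's excess over chi2_hat)."""

    v: np.ndarray
    s2: float


def _geodesic_rhs(Gamma: np.ndarray, N: int):
    def f(tau, z):
        xi = z[N:]
        acc = -np.einsum("uab,a,b->u", Gamma, xi, xi)
        return np.concatenate([xi, acc])

    return f


def _escape_event(theta_bound: float, xi_bound: float, N: int):
    def event(tau, z):
        return 1.0 - max(
            np.max(np.abs(z[:N])) / theta_bound, np.max(np.abs(z[N : 2 * N])) / xi_bound
        )

    event.terminal = True
    event.direction = -1.0
    return event


def geodesic_shoot(
    snapshot: GeometrySnapshot,
    v: np.ndarray,
    tau_end: float = 1.0,
    t_eval: np.ndarray | None = None,
) -> GeodesicSolution:
    """Integrate the frozen-Christoffel geodesic IVP from (theta_hat, v).

    The solution is declared diverged when theta or the velocity xi escapes
    its norm bound before tau_end; the escape time tau_star is then the
    (event-located) blow-up time.
    """
    if not 0 < tau_end:
        raise ValueError("tau_end must be positive")
    N = snapshot.N
    v = np.atleast_1d(np.asarray(v, dtype=float))
    z0 = np.concatenate([snapshot.theta_hat.values, v])
    sol = solve_ivp(
        _geodesic_rhs(snapshot.christoffel.Gamma, N),
        (0.0, tau_end),
        z0,
        method="DOP853",
        rtol=snapshot.rtol,
        atol=snapshot.atol,
        t_eval=t_eval,
        events=_escape_event(snapshot.theta_bound, snapshot.xi_bound, N),
    )
    diverged = len(sol.t_events[0]) > 0
    if not diverged and not sol.success:
        raise RuntimeError(f"geodesic integration failed: {sol.message}")
    return GeodesicSolution(
        tau_grid=sol.t,
        theta_path=sol.y[:N].T,
        velocity_path=sol.y[N:].T,
        initial_velocity=v,
        diverged=diverged,
        tau_star=float(sol.t_events[0][0]) if diverged else None,
    )


def _shoot_end(snapshot: GeometrySnapshot, v: np.ndarray, with_jac: bool):
    """Endpoint theta(1) of the geodesic, optionally with the sensitivity
    d theta(1)/d v from the variational equations.  Returns
    (theta1 | None, Phi | None, diverged, tau_star)."""
    N = snapshot.N
    Gamma = snapshot.christoffel.Gamma
    if with_jac:
        z0 = np.concatenate(
            [snapshot.theta_hat.values, v, np.zeros(N * N), np.eye(N).ravel()]
        )

        def f(tau, z):
            xi = z[N : 2 * N]
            Pt = z[2 * N : 2 * N + N * N].reshape(N, N)
            Px = z[2 * N + N * N :].reshape(N, N)
            acc = -np.einsum("uab,a,b->u", Gamma, xi, xi)
            dPx = -2.0 * np.einsum("uab,a,bk->uk", Gamma, xi, Px)
            return np.concatenate([xi, acc, Px.ravel(), dPx.ravel()])

    else:
        z0 = np.concatenate([snapshot.theta_hat.values, v])
        f = _geodesic_rhs(Gamma, N)

    sol = solve_ivp(
        f,
        (0.0, 1.0),
        z0,
        method="DOP853",
        rtol=snapshot.rtol,
        atol=snapshot.atol,
        events=_escape_event(snapshot.theta_bound, snapshot.xi_bound, N),
    )
    if len(sol.t_events[0]) > 0:
        return None, None, True, float(sol.t_events[0][0])
    if not sol.success:
        raise RuntimeError(f"geodesic integration failed: {sol.message}")
    theta1 = sol.y[:N, -1]
    Phi = sol.y[2 * N : 2 * N + N * N, -1].reshape(N, N) if with_jac else None
    return theta1, Phi, False, None


def _pull_into_domain(snapshot: GeometrySnapshot, v: np.ndarray) -> np.ndarray:
    """Shrink v along its ray until the geodesic no longer blows up before
    tau = 1 (uses the exact rescaling theta_{cv}(tau) = theta_v(c tau))."""
    for _ in range(200):
        _, _, diverged, tau_star = _shoot_end(snapshot, v, with_jac=False)
        if not diverged:
            return v
        v = v * (0.95 * tau_star)
    raise BVPError("could not find a non-divergent initial velocity along the target ray")


def _newton_bvp(
    snapshot: GeometrySnapshot,
    target: np.ndarray,
    v0: np.ndarray,
    tol: float,
    max_iter: int = 80,
) -> tuple[np.ndarray | None, float]:
    """Damped Newton shooting for theta(1) = target; returns (v, residual)
    with v = None on failure."""
    # all residuals come from the variational-augmented system: near a
    # blow-up the integration bias is amplified with the solution, so
    # mixing systems with different step sequences would put an artificial
    # floor under the Newton residual
    try:
        v = _pull_into_domain(snapshot, np.asarray(v0, dtype=float).copy())
    except BVPError:
        return None, math.inf
    theta1, Phi, _, _ = _shoot_end(snapshot, v, with_jac=True)
    Fn = float(np.linalg.norm(theta1 - target))
    best = Fn
    for _ in range(max_iter):
        if Fn < tol:
            return v, Fn
        try:
            dv = np.linalg.solve(Phi, target - theta1)
        except np.linalg.LinAlgError:
            return None, best
        alpha, accepted = 1.0, False
        while alpha > 2.0**-12:
            v_try = v + alpha * dv
            theta_try, Phi_try, diverged, _ = _shoot_end(snapshot, v_try, with_jac=True)
            if not diverged:
                F_try = float(np.linalg.norm(theta_try - target))
                if F_try < Fn:
                    v, Fn, accepted = v_try, F_try, True
                    theta1, Phi = theta_try, Phi_try
                    break
            alpha *= 0.5
        if not accepted:
            return None, best
        best = min(best, Fn)
    return (v, Fn) if Fn < tol else (None, min(best, Fn))


def _collocation_bvp(
    snapshot: GeometrySnapshot, target: np.ndarray, tol: float
) -> np.ndarray | None:
    """Collocation fallback (scipy.solve_bvp) on the first-order system."""
    N = snapshot.N
    theta_hat = snapshot.theta_hat.values
    Gamma = snapshot.christoffel.Gamma

    def fun(tau, z):
        xi = z[N:]
        acc = -np.einsum("uab,at,bt->ut", Gamma, xi, xi)
        return np.vstack([xi, acc])

    def bc(za, zb):
        return np.concatenate([za[:N] - theta_hat, zb[:N] - target])

    tau = np.linspace(0, 1, 21)
    guess = np.vstack(
        [
            theta_hat[:, None] + (target - theta_hat)[:, None] * tau[None, :],
            np.tile((target - theta_hat)[:, None], (1, len(tau))),
        ]
    )
    try:
        with np.errstate(all="ignore"):
            sol = solve_bvp(fun, bc, tau, guess, tol=min(tol, 1e-8), max_nodes=1500)
    except Exception:
        return None
    return sol.y[N:, 0] if sol.success else None


def rnc_map(
    snapshot: GeometrySnapshot,
    theta_star,
    v0: np.ndarray | None = None,
    max_iter: int = 80,
) -> RNCPoint:
    """Map a parameter point to Riemann normal coordinates.

    Solves the two-point BVP theta(0) = theta_hat, theta(1) = theta_star for
    the frozen-Christoffel geodesic and returns v = theta_dot(0).  The
    flat-manifold velocity v = theta_star - theta_hat (exact for vanishing
    Christoffel symbols) seeds a damped Newton shooting method with the
    endpoint sensitivity obtained from the variational equations; a
    continuation over intermediate targets and a collocation solver serve as
    fallbacks.  Raises :class:`BVPError` if no geodesic reaches theta_star,
    which typically means the point lies beyond the boundary of the
    approximated manifold.
    """
    target = (
        theta_star.values
        if isinstance(theta_star, ParameterVector)
        else np.atleast_1d(np.asarray(theta_star, dtype=float))
    )
    if not np.all(np.isfinite(target)):
        raise ValueError("theta_star must be finite")
    theta_hat = snapshot.theta_hat.values
    tol = snapshot.bvp_tol * max(1.0, float(np.linalg.norm(target)))
    g = snapshot.metric.g

    def make_point(v: np.ndarray) -> RNCPoint:
        return RNCPoint(v=v, s2=float(v @ g @ v))

    guess = v0 if v0 is not None else target - theta_hat
    v, best = _newton_bvp(snapshot, target, guess, tol, max_iter=max_iter)
    if v is not None:
        return make_point(v)

    # continuation: walk the target from theta_hat toward theta_star
    delta = target - theta_hat
    s_done, step, v_warm = 0.0, 1.0, np.zeros_like(delta)
    while s_done < 1.0 and step > 1e-3:
        s_try = min(1.0, s_done + step)
        v_try, res = _newton_bvp(snapshot, theta_hat + s_try * delta, v_warm, tol, max_iter=20)
        if v_try is not None:
            s_done, v_warm = s_try, v_try
            step = min(1.5 * step, 1.0 - s_done) if s_done < 1.0 else step
            best = min(best, res)
        else:
            step *= 0.5
    if s_done >= 1.0:
        return make_point(v_warm)
    if s_done > 0.0:
        # one full-strength attempt from the most advanced warm start
        v, res = _newton_bvp(snapshot, target, v_warm, tol, max_iter=max_iter)
        if v is not None:
            return make_point(v)
        best = min(best, res)

    v_c = _collocation_bvp(snapshot, target, tol)
    if v_c is not None:
        v, res = _newton_bvp(snapshot, target, v_c, tol, max_iter=20)
        if v is not None:
            return make_point(v)
        best = min(best, res)
    raise BVPError(
        f"geodesic BVP to theta* = {np.round(target, 6).tolist()} did not converge "
        f"(best boundary residual {best:.3g}); theta* may lie beyond the boundary "
        "of the approximated model manifold",
        best_residual=best,
    )


# ---------------------------------------------------------------------------
# surrogate objective


def surrogate_chi2(snapshot: GeometrySnapshot, theta, v0: np.ndarray | None = None) -> float:
    """chi2_tilde(theta) = chi2_hat + v(theta)^T g_hat v(theta)."""
    return snapshot.chi2_hat + rnc_map(snapshot, theta, v0=v0).s2


def surrogate_gradient_hessian(
    snapshot: GeometrySnapshot,
    theta,
    step_rel: float = 1e-5,
    v0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Gauss-Newton Hessian of the surrogate objective.

    dv/dtheta is obtained by central finite differences of the BVP map
    (warm-started from v(theta)); then grad = 2 (dv/dtheta)^T g v and
    hess = 2 (dv/dtheta)^T g (dv/dtheta).
    """
    values = (
        theta.values if isinstance(theta, ParameterVector) else np.atleast_1d(np.asarray(theta, float))
    )
    N = snapshot.N
    base = rnc_map(snapshot, values, v0=v0).v
    dvdtheta = np.empty((N, N))
    for k in range(N):
        h = step_rel * max(abs(values[k]), 1.0)
        up, dn = values.copy(), values.copy()
        up[k] += h
        dn[k] -= h
        v_up = rnc_map(snapshot, up, v0=base).v
        v_dn = rnc_map(snapshot, dn, v0=base).v
        dvdtheta[:, k] = (v_up - v_dn) / (2.0 * h)
    g = snapshot.metric.g
    grad = 2.0 * dvdtheta.T @ (g @ base)
    hess = 2.0 * dvdtheta.T @ g @ dvdtheta
    return grad, hess


class SurrogateObjective:
    """Callable surrogate objective with a warm-started BVP cache.

    Successive evaluations at nearby points (as in profile walks or nuisance
    optimizations) reuse the previous initial velocity as the Newton seed.
    """

    def __init__(self, snapshot: GeometrySnapshot):
        self.snapshot = snapshot
        self._v_warm: np.ndarray | None = None

    def evaluate(self, theta) -> float:
        point = rnc_map(self.snapshot, theta, v0=self._v_warm)
        self._v_warm = point.v
        return self.snapshot.chi2_hat + point.s2

    __call__ = evaluate

    def gradient(self, theta) -> np.ndarray:
        grad, _ = surrogate_gradient_hessian(self.snapshot, theta, v0=self._v_warm)
        return grad

    def gradient_hessian(self, theta) -> tuple[np.ndarray, np.ndarray]:
        return surrogate_gradient_hessian(self.snapshot, theta, v0=self._v_warm)

    def profile_min(
        self, i: int, target: float, max_iter: int = 40
    ) -> tuple[float, np.ndarray] | None:
        """Nuisance-minimized surrogate value with parameter i held at target.

        In RNC the surrogate is exactly quadratic, so the profile point is
        min_v v^T g v subject to theta(1; v)_i = target — solved here by a
        Gauss-Newton KKT iteration on (v, lambda) where each step costs one
        forward geodesic shoot with endpoint sensitivities.  Returns
        (value, full theta(1)) or None when the target slice is unreachable
        (beyond the approximated manifold boundary).
        """
        out = self._profile_min_from(
            i, target, self._v_warm.copy() if self._v_warm is not None else None, max_iter
        )
        if out is None and self._v_warm is not None:
            out = self._profile_min_from(i, target, None, max_iter)  # cold restart
        return out

    def _profile_min_from(
        self, i: int, target: float, v_start: np.ndarray | None, max_iter: int
    ) -> tuple[float, np.ndarray] | None:
        snap = self.snapshot
        g = snap.metric.g
        N = snap.N
        tol = snap.bvp_tol * max(1.0, abs(target))
        v = v_start if v_start is not None else np.zeros(N)
        lam = 0.0
        theta1, Phi, diverged, _ = _shoot_end(snap, v, with_jac=True)
        if diverged:
            try:
                v = _pull_into_domain(snap, v)
            except BVPError:
                return None
            theta1, Phi, _, _ = _shoot_end(snap, v, with_jac=True)
        tol_c = max(tol, 1e-6 * max(1.0, abs(target)))
        stall = 0
        c_best = math.inf
        mu = 0.0  # Levenberg damping: bounds the step's metric-flat component
        damp_scale = max(1.0, np.trace(2.0 * g) / N)
        best: tuple[float, np.ndarray, np.ndarray] | None = None  # (value, v, theta1)

        def finish():
            if best is None:
                return None
            self._v_warm = best[1]
            return snap.chi2_hat + best[0], best[2]

        for _ in range(max_iter):
            c = theta1[i] - target
            val = float(v @ g @ v)
            if abs(c) < tol_c:
                if best is not None and val > best[0] - 1e-6 * max(1.0, best[0]):
                    # feasible and no longer improving: converged in value
                    if val < best[0]:
                        best = (val, v.copy(), theta1.copy())
                    return finish()
                if best is None or val < best[0]:
                    best = (val, v.copy(), theta1.copy())
            if abs(c) < max(0.98 * c_best, tol_c):
                c_best, stall = min(c_best, abs(c)), 0
            else:
                stall += 1
                if stall >= 6:
                    return finish()
            r1 = 2.0 * g @ v + lam * Phi[i]
            accepted = False
            for _attempt in range(8):
                K = np.zeros((N + 1, N + 1))
                K[:N, :N] = 2.0 * g + mu * damp_scale * np.eye(N)
                K[:N, N] = Phi[i]
                K[N, :N] = Phi[i]
                try:
                    sol = np.linalg.solve(K, -np.concatenate([r1, [c]]))
                except np.linalg.LinAlgError:
                    return finish()
                dv, dlam = sol[:N], sol[N]
                for alpha in (1.0, 0.5, 0.25, 0.125):
                    v_try = v + alpha * dv
                    theta_try, Phi_try, div, _ = _shoot_end(snap, v_try, with_jac=True)
                    if div:
                        continue
                    c_try = theta_try[i] - target
                    if abs(c_try) < abs(c) * (1.0 - 0.05 * alpha) + 0.5 * tol_c or (
                        abs(c) < tol_c
                        and abs(c_try) < tol_c
                        and v_try @ g @ v_try < v @ g @ v
                    ):
                        v, lam = v_try, lam + alpha * dlam
                        theta1, Phi = theta_try, Phi_try
                        accepted = True
                        break
                if accepted:
                    mu = 0.0 if mu < 1e-12 else 0.3 * mu
                    break
                mu = max(10.0 * mu, 1e-4)
            if not accepted:
                return finish()
        return finish()


# ---------------------------------------------------------------------------
# closed-form oracle and boundary scan


def model1_closed_form(v: float, tau: float) -> float:
    """Exact geodesic theta(tau) = -log(1 - v tau) for the one-parameter
    exponential model with the single unit datum; the analytic oracle for
    geodesic shooting and the RNC map on that model."""
    x = 1.0 - v * tau
    if x <= 0:
        raise ValueError(
            f"v * tau = {v * tau:g} >= 1: the geodesic has reached the manifold boundary"
        )
    return -math.log(x)


def boundary_scan(
    snapshot: GeometrySnapshot,
    direction: Sequence[float],
    v_max: float = 1e3,
    n_steps: int = 80,
    rel_tol: float = 1e-9,
) -> float:
    """Distance to the manifold boundary along a direction, in units of the
    g_hat-norm of the initial velocity (equivalently, arc length).

    Bisects on the speed c for the smallest c at which the geodesic with
    initial velocity c * direction blows up before tau = 1.  Returns
    ``math.inf`` when no speed up to v_max diverges (unbounded direction).
    """
    d = np.atleast_1d(np.asarray(direction, dtype=float))
    gnorm = math.sqrt(float(d @ snapshot.metric.g @ d))
    if gnorm <= 0:
        raise ValueError("direction must have positive g-norm")
    d = d / gnorm

    def diverges(c: float) -> bool:
        _, _, div, _ = _shoot_end(snapshot, c * d, with_jac=False)
        return div

    if not diverges(v_max):
        return math.inf
    lo, hi = 0.0, v_max
    for _ in range(n_steps):
        if hi - lo <= rel_tol * max(1.0, hi):
            break
        mid = 0.5 * (lo + hi)
        if diverges(mid):
            hi = mid
        else:
            lo = mid
    return hi
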