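"""Parametric prediction models, residuals, and residual sensitivities.

A model maps ``(t, theta, condition) -> y``.  Two kinds are supported:

* closed-form models, defined by a sympy expression (analytic first- and
  second-order derivatives are generated symbolically), and
* mass-action ODE models, for which first-order sensitivities are obtained
  by integrating the forward sensitivity equations alongside the model ODE
  and second-order sensitivities by central finite differences of the
  first-order ones.

All sensitivities are reported for the *normalized residual*
``r_m = (y_D,m - y(t_m, theta)) / sigma_m``, the map whose image is the
model manifold in data space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp


class ModelError(RuntimeError):
    """Base class for model-evaluation failures."""


class ModelEvaluationError(ModelError):
    """Raised when an ODE integration fails; names the condition and theta."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class ParameterVector:
    """An ordered, named, box-bounded parameter vector theta in R^N."""

    values: np.ndarray
    names: list[str]
    bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        self.names = list(self.names)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")
        if self.bounds is None:
            self.bounds = np.tile([-np.inf, np.inf], (len(self.names), 1))
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(len(self.names), 2)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ValueError(
                f"parameter values {self.values} violate bounds {self.bounds.tolist()}"
            )

    @property
    def N(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(np.asarray(values, dtype=float), self.names, self.bounds.copy())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def copy(self) -> "ParameterVector":
        return self.with_values(self.values.copy())


_DATASET_COLUMNS = ["time", "value", "sigma", "condition", "observable"]


@dataclass
class Dataset:
    """Observations (t, y_D, sigma, condition[, observable]) as a DataFrame.

    ``condition`` selects per-condition model inputs (e.g. an initial enzyme
    concentration); ``observable`` selects which model output the record
    measures (ignored by single-output models).  Residuals concatenate all
    records into one M-vector in row order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("time", "value", "sigma"):
            if col not in df.columns:
                raise ValueError(f"dataset is missing required column '{col}'")
        if "condition" not in df.columns:
            df["condition"] = ""
        if "observable" not in df.columns:
            df["observable"] = ""
        df["condition"] = df["condition"].fillna("").astype(str)
        df["observable"] = df["observable"].fillna("").astype(str)
        df = df[_DATASET_COLUMNS].reset_index(drop=True)
        if len(df) < 1:
            raise ValueError("dataset must contain at least one record")
        if not np.all(df["sigma"].to_numpy(dtype=float) > 0):
            raise ValueError("all sigma values must be strictly positive")
        self.frame = df

    @classmethod
    def from_arrays(
        cls,
        time: Sequence[float],
        value: Sequence[float],
        sigma: Sequence[float] | float,
        condition: Sequence[str] | str = "",
        observable: Sequence[str] | str = "",
    ) -> "Dataset":
        time = np.asarray(time, dtype=float)
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), time.shape)
        if isinstance(condition, str):
            condition = [condition] * len(time)
        if isinstance(observable, str):
            observable = [observable] * len(time)
        return cls(
            pd.DataFrame(
                {
                    "time": time,
                    "value": np.asarray(value, dtype=float),
                    "sigma": sigma,
                    "condition": list(condition),
                    "observable": list(observable),
                }
            )
        )

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def M(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def value(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.frame["sigma"].to_numpy(dtype=float)


@dataclass
class SensitivityBundle:
    """Residuals with first- and second-order parameter sensitivities.

    ``J[m, mu] = dr_m/dtheta_mu`` and ``H[m, a, b] = d2 r_m/dtheta_a dtheta_b``
    (symmetric in its last two indices).
    """

    r: np.ndarray
    J: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        M = len(self.r)
        if self.J.shape[0] != M or self.H.shape[0] != M:
            raise ValueError("inconsistent shapes in SensitivityBundle")
        if self.H.shape[1] != self.H.shape[2] or self.H.shape[1] != self.J.shape[1]:
            raise ValueError("inconsistent shapes in SensitivityBundle")


# ---------------------------------------------------------------------------
# model specifications


class ModelSpec:
    """A parametric prediction model with sensitivity providers."""

    kind: str = "closed_form"
    name: str = "model"
    param_names: list[str]
    default_bounds: np.ndarray

    def parameter_vector(
        self, values: Sequence[float], bounds: np.ndarray | None = None
    ) -> ParameterVector:
        if bounds is None:
            bounds = self.default_bounds.copy()
        return ParameterVector(np.asarray(values, dtype=float), self.param_names, bounds)

    @property
    def N(self) -> int:
        return len(self.param_names)

    def predict(self, t, theta, condition: str = "", observable: str | None = None):
        raise NotImplementedError

    def predictions(self, theta_values: np.ndarray, data: Dataset) -> np.ndarray:
        raise NotImplementedError

    def prediction_jacobian(
        self, theta_values: np.ndarray, data: Dataset
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (y, dy/dtheta) with shapes (M,) and (M, N)."""
        raise NotImplementedError

    def prediction_hessian(self, theta_values: np.ndarray, data: Dataset) -> np.ndarray | None:
        """Analytic (M, N, N) second derivatives, or None if unavailable."""
        return None


class ClosedFormModel(ModelSpec):
    """Model defined by a sympy expression; derivatives generated symbolically."""

    kind = "closed_form"

    def __init__(
        self,
        name: str,
        expr: sp.Expr,
        t_symbol: sp.Symbol,
        param_symbols: Sequence[sp.Symbol],
        bounds: Sequence[Sequence[float]] | None = None,
    ) -> None:
        self.name = name
        self.expr = expr
        self.param_names = [str(s) for s in param_symbols]
        n = len(self.param_names)
        self.default_bounds = (
            np.tile([-np.inf, np.inf], (n, 1)) if bounds is None else np.asarray(bounds, float)
        )
        args = (t_symbol, *param_symbols)
        self._y = sp.lambdify(args, expr, "numpy")
        self._dy = [sp.lambdify(args, sp.diff(expr, s), "numpy") for s in param_symbols]
        self._d2y = [
            [sp.lambdify(args, sp.diff(expr, a, b), "numpy") for b in param_symbols]
            for a in param_symbols
        ]

    @staticmethod
    def _broadcast(value, t: np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float), np.shape(t)).copy()

    def predict(self, t, theta, condition: str = "", observable: str | None = None):
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = self._broadcast(self._y(np.asarray(t, dtype=float), *theta), np.asarray(t))
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    def predictions(self, theta_values: np.ndarray, data: Dataset) -> np.ndarray:
        t = data.time
        return self._broadcast(self._y(t, *theta_values), t)

    def prediction_jacobian(self, theta_values, data):
        t = data.time
        y = self._broadcast(self._y(t, *theta_values), t)
        dy = np.column_stack([self._broadcast(f(t, *theta_values), t) for f in self._dy])
        return y, dy

    def prediction_hessian(self, theta_values, data):
        t = data.time
        n = self.N
        H = np.empty((len(t), n, n))
        for a in range(n):
            for b in range(n):
                H[:, a, b] = self._broadcast(self._d2y[a][b](t, *theta_values), t)
        return H


class LinearBasisModel(ModelSpec):
    """Linear model y = sum_i theta_i b_i(t) for a supplied basis."""

    kind = "closed_form"

    def __init__(self, basis: Sequence[Callable[[np.ndarray], np.ndarray]], name: str = "linear"):
        self.name = name
        self.basis = list(basis)
        self.param_names = [f"theta{i}" for i in range(len(self.basis))]
        self.default_bounds = np.tile([-np.inf, np.inf], (len(self.basis), 1))

    def _design(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.column_stack(
            [np.broadcast_to(np.asarray(b(t), dtype=float), t.shape) for b in self.basis]
        )

    def predict(self, t, theta, condition: str = "", observable: str | None = None):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = self._design(t_arr) @ np.asarray(theta, dtype=float)
        return float(out[0]) if np.ndim(t) == 0 else out

    def predictions(self, theta_values, data):
        return self._design(data.time) @ theta_values

    def prediction_jacobian(self, theta_values, data):
        B = self._design(data.time)
        return B @ theta_values, B

    def prediction_hessian(self, theta_values, data):
        return np.zeros((data.M, self.N, self.N))


class ODEModel(ModelSpec):
    """Mass-action ODE model with forward sensitivity equations.

    ``rhs``, ``dfdx`` and ``dfdtheta`` take ``(t, x, theta, cond)`` where
    ``cond`` is the per-condition input mapping; ``x0``/``dx0dtheta`` take
    ``(theta, cond)``.  Observables are linear read-outs of single states.
    """

    kind = "ode"

    def __init__(
        self,
        name: str,
        state_names: Sequence[str],
        param_names: Sequence[str],
        rhs: Callable,
        dfdx: Callable,
        dfdtheta: Callable,
        x0: Callable,
        dx0dtheta: Callable,
        observables: dict[str, int],
        default_observable: str,
        conditions: dict[str, dict] | None = None,
        bounds: Sequence[Sequence[float]] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> None:
        self.name = name
        self.state_names = list(state_names)
        self.param_names = list(param_names)
        self.rhs = rhs
        self.dfdx = dfdx
        self.dfdtheta = dfdtheta
        self.x0 = x0
        self.dx0dtheta = dx0dtheta
        self.observables = dict(observables)
        self.default_observable = default_observable
        self.conditions = conditions if conditions is not None else {"": {}}
        n = len(self.param_names)
        self.default_bounds = (
            np.tile([-np.inf, np.inf], (n, 1)) if bounds is None else np.asarray(bounds, float)
        )
        self.rtol = rtol
        self.atol = atol

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def _condition_inputs(self, label: str) -> dict:
        if label in self.conditions:
            return self.conditions[label]
        if label == "" and len(self.conditions) == 1:
            return next(iter(self.conditions.values()))
        raise ModelEvaluationError(
            f"unknown condition '{label}' for model '{self.name}'; "
            f"known conditions: {sorted(self.conditions)}"
        )

    def _observable_index(self, label: str) -> int:
        label = label or self.default_observable
        try:
            return self.observables[label]
        except KeyError:
            raise ModelEvaluationError(
                f"unknown observable '{label}'; known: {sorted(self.observables)}"
            ) from None

    def _solve(
        self, theta: np.ndarray, times: np.ndarray, cond_label: str, with_sens: bool
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Integrate from t=0 to max(times); returns states (n, T) and,
        if requested, sensitivities (n, N, T) from the forward equations."""
        cond = self._condition_inputs(cond_label)
        n, N = self.n_states, self.N
        x_init = np.asarray(self.x0(theta, cond), dtype=float)
        t_eval = np.asarray(times, dtype=float)
        t_end = float(t_eval.max()) if len(t_eval) else 0.0

        if with_sens:
            z0 = np.concatenate([x_init, np.asarray(self.dx0dtheta(theta, cond), float).ravel()])

            def f(t, z):
                x = z[:n]
                S = z[n:].reshape(n, N)
                fx = np.asarray(self.rhs(t, x, theta, cond), dtype=float)
                A = np.asarray(self.dfdx(t, x, theta, cond), dtype=float)
                B = np.asarray(self.dfdtheta(t, x, theta, cond), dtype=float)
                return np.concatenate([fx, (A @ S + B).ravel()])

        else:
            z0 = x_init

            def f(t, z):
                return np.asarray(self.rhs(t, z, theta, cond), dtype=float)

        sol = solve_ivp(
            f,
            (0.0, max(t_end, 0.0)),
            z0,
            method="LSODA",
            t_eval=t_eval,
            rtol=self.rtol,
            atol=self.atol,
        )
        if not sol.success:
            raise ModelEvaluationError(
                f"ODE integration failed for model '{self.name}', condition "
                f"'{cond_label}', theta={theta.tolist()}: {sol.message}"
            )
        states = sol.y[:n]
        sens = sol.y[n:].reshape(n, N, -1) if with_sens else None
        return states, sens

    def predict(self, t, theta, condition: str = "", observable: str | None = None):
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        order = np.argsort(t_arr)
        states, _ = self._solve(theta, t_arr[order], condition, with_sens=False)
        idx = self._observable_index(observable or "")
        out = np.empty_like(t_arr)
        out[order] = states[idx]
        return float(out[0]) if np.ndim(t) == 0 else out

    def _grouped(self, data: Dataset):
        df = data.frame
        for cond_label in df["condition"].unique():
            rows = np.flatnonzero((df["condition"] == cond_label).to_numpy())
            times = df["time"].to_numpy(dtype=float)[rows]
            uniq, inv = np.unique(times, return_inverse=True)
            obs_idx = np.array(
                [self._observable_index(df["observable"].iat[r]) for r in rows], dtype=int
            )
            yield cond_label, rows, uniq, inv, obs_idx

    def predictions(self, theta_values, data):
        y = np.empty(data.M)
        for cond_label, rows, uniq, inv, obs_idx in self._grouped(data):
            states, _ = self._solve(theta_values, uniq, cond_label, with_sens=False)
            y[rows] = states[obs_idx, inv]
        return y

    def prediction_jacobian(self, theta_values, data):
        y = np.empty(data.M)
        dy = np.empty((data.M, self.N))
        for cond_label, rows, uniq, inv, obs_idx in self._grouped(data):
            states, sens = self._solve(theta_values, uniq, cond_label, with_sens=True)
            y[rows] = states[obs_idx, inv]
            dy[rows] = sens[obs_idx, :, inv]
        return y, dy


class LogScaleModel(ModelSpec):
    """Chart change to log-parameters u = log(theta) by the chain rule.

    The Christoffel symbols (and hence the surrogate) depend on the chart;
    this wrapper makes the chart explicit rather than implicit.
    """

    def __init__(self, base: ModelSpec) -> None:
        self.base = base
        self.kind = base.kind
        self.name = f"log_{base.name}"
        self.param_names = [f"log_{p}" for p in base.param_names]
        lo = base.default_bounds[:, 0]
        hi = base.default_bounds[:, 1]
        if np.any(lo < 0):
            raise ValueError("log reparameterization requires non-negative lower bounds")
        with np.errstate(divide="ignore"):
            self.default_bounds = np.column_stack([np.log(lo), np.log(hi)])

    def _theta(self, u: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(u, dtype=float))

    def predict(self, t, u, condition: str = "", observable: str | None = None):
        return self.base.predict(t, self._theta(u), condition, observable)

    def predictions(self, u, data):
        return self.base.predictions(self._theta(u), data)

    def prediction_jacobian(self, u, data):
        theta = self._theta(u)
        y, dy = self.base.prediction_jacobian(theta, data)
        return y, dy * theta[None, :]

    def prediction_hessian(self, u, data):
        theta = self._theta(u)
        Hy = self.base.prediction_hessian(theta, data)
        if Hy is None:
            return None
        _, dy = self.base.prediction_jacobian(theta, data)
        H = Hy * theta[None, :, None] * theta[None, None, :]
        for k in range(self.N):
            H[:, k, k] += dy[:, k] * theta[k]
        return H


# ---------------------------------------------------------------------------
# residual operations


def _theta_values(theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.values
    return np.atleast_1d(np.asarray(theta, dtype=float))


def residuals(model: ModelSpec, theta, data: Dataset) -> np.ndarray:
    """Normalized residuals r_m = (y_D,m - y(t_m, theta)) / sigma_m."""
    y = model.predictions(_theta_values(theta), data)
    return (data.value - y) / data.sigma


def first_order_sensitivities(model: ModelSpec, theta, data: Dataset) -> np.ndarray:
    """J[m, mu] = dr_m/dtheta_mu (analytic for closed forms, sensitivity
    equations for ODE models)."""
    _, dy = model.prediction_jacobian(_theta_values(theta), data)
    return -dy / data.sigma[:, None]


def second_order_sensitivities(
    model: ModelSpec,
    theta,
    data: Dataset,
    step: float = 1e-4,
    force_finite_differences: bool = False,
) -> np.ndarray:
    """H[m, a, b] = d2 r_m / dtheta_a dtheta_b, symmetrized over (a, b).

    Closed-form models use their symbolic second derivatives unless
    ``force_finite_differences`` is set; otherwise central finite
    differences of the first-order sensitivities with per-parameter step
    ``step * max(|theta_k|, 1)`` are used.
    """
    values = _theta_values(theta)
    if not force_finite_differences:
        Hy = model.prediction_hessian(values, data)
        if Hy is not None:
            return -Hy / data.sigma[:, None, None]

    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    N = len(values)
    bounds = theta.bounds if isinstance(theta, ParameterVector) else None
    H = np.empty((len(data.frame), N, N))
    for k in range(N):
        h = step * max(abs(values[k]), 1.0)
        if bounds is not None and (
            values[k] - h < bounds[k, 0] or values[k] + h > bounds[k, 1]
        ):
            raise ValueError(
                f"parameter '{k}' is within the finite-difference step {h:g} of a "
                "bound; use a smaller step or a one-sided scheme"
            )
        up, dn = values.copy(), values.copy()
        up[k] += h
        dn[k] -= h
        Jp = first_order_sensitivities(model, up, data)
        Jm = first_order_sensitivities(model, dn, data)
        H[:, :, k] = (Jp - Jm) / (2.0 * h)
    return 0.5 * (H + np.swapaxes(H, 1, 2))


def sensitivity_bundle(
    model: ModelSpec, theta, data: Dataset, step: float = 1e-4
) -> SensitivityBundle:
    """Residuals with first- and second-order sensitivities at theta."""
    return SensitivityBundle(
        r=residuals(model, theta, data),
        J=first_order_sensitivities(model, theta, data),
        H=second_order_sensitivities(model, theta, data, step=step),
    )


# ---------------------------------------------------------------------------
# built-in models


def _enzyme_model(
    conditions: dict[str, dict] | None,
    observables: Sequence[str] | None,
) -> ODEModel:
    # states [S, E, C, P]; theta = (k1, k2, k3, S0); condition supplies E0
    def rhs(t, x, th, cond):
        S, E, C, P = x
        k1, k2, k3, _ = th
        b = k1 * S * E
        d = (k2 + k3) * C
        return np.array([-b + k2 * C, -b + d, b - d, k3 * C])

    def dfdx(t, x, th, cond):
        S, E, C, P = x
        k1, k2, k3, _ = th
        return np.array(
            [
                [-k1 * E, -k1 * S, k2, 0.0],
                [-k1 * E, -k1 * S, k2 + k3, 0.0],
                [k1 * E, k1 * S, -(k2 + k3), 0.0],
                [0.0, 0.0, k3, 0.0],
            ]
        )

    def dfdtheta(t, x, th, cond):
        S, E, C, P = x
        return np.array(
            [
                [-S * E, C, 0.0, 0.0],
                [-S * E, C, C, 0.0],
                [S * E, -C, -C, 0.0],
                [0.0, 0.0, C, 0.0],
            ]
        )

    def x0(th, cond):
        return np.array([th[3], float(cond.get("E0", 1.0)), 0.0, 0.0])

    def dx0dtheta(th, cond):
        D = np.zeros((4, 4))
        D[0, 3] = 1.0
        return D

    obs_names = list(observables) if observables is not None else ["S", "P"]
    state_index = {"S": 0, "E": 1, "C": 2, "P": 3}
    return ODEModel(
        name="enzyme",
        state_names=["S", "E", "C", "P"],
        param_names=["k1", "k2", "k3", "S0"],
        rhs=rhs,
        dfdx=dfdx,
        dfdtheta=dfdtheta,
        x0=x0,
        dx0dtheta=dx0dtheta,
        observables={k: state_index[k] for k in obs_names},
        default_observable=obs_names[-1],
        conditions=conditions,
        bounds=[[0.0, np.inf]] * 4,
    )


def builtin_model(
    name: str,
    *,
    n: int | None = None,
    basis: Sequence[Callable] | None = None,
    conditions: dict[str, dict] | None = None,
    observables: Sequence[str] | None = None,
) -> ModelSpec:
    """Construct one of the built-in models.

    ``exp_fixed``   y = exp(-k1 t), k1 unrestricted
    ``exp_decay``   y = A0 exp(-k1 t), k1, A0 >= 0
    ``enzyme``      mass-action enzyme kinetics (states S, E, C, P)
    ``linear``      y = sum_i theta_i b_i(t) for the supplied basis
    ``reciprocal``  y = 1/theta, theta > 0
    ``power``       y = theta**n for a supplied odd integer n
    """
    t, k1, A0, th = sp.symbols("t k1 A0 theta")
    if name == "exp_fixed":
        return ClosedFormModel("exp_fixed", sp.exp(-k1 * t), t, [k1])
    if name == "exp_decay":
        return ClosedFormModel(
            "exp_decay", A0 * sp.exp(-k1 * t), t, [k1, A0], bounds=[[0, np.inf], [0, np.inf]]
        )
    if name == "reciprocal":
        return ClosedFormModel("reciprocal", 1 / th, t, [th], bounds=[[0, np.inf]])
    if name == "power":
        n = 3 if n is None else int(n)
        if n % 2 == 0:
            raise ValueError("power model requires an odd integer exponent")
        return ClosedFormModel(f"power{n}", th**n, t, [th])
    if name == "linear":
        return LinearBasisModel(basis if basis is not None else [lambda t: np.ones_like(t), lambda t: t])
    if name == "enzyme":
        return _enzyme_model(conditions, observables)
    raise ValueError(f"unknown built-in model '{name}'")
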