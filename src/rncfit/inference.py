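"""Maximum-likelihood fitting, profile likelihood, and identifiability calls.

The chi-square objective chi2(theta) = sum_m ((y_D,m - y(t_m, theta))/sigma_m)^2
is minimized with a multistart gradient-based optimizer.  Profiles walk one
parameter outward from the optimum in both directions with adaptive steps,
re-optimizing the remaining (nuisance) parameters warm-started from the
previous grid point, and stop on a threshold crossing, a parameter bound, a
surrogate-domain boundary, or after the profiled parameter has moved six
orders of magnitude without crossing (the operational definition of a
practically non-identifiable direction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import qmc

from .geometry import BVPError, GeometrySnapshot, SurrogateObjective
from .models import (
    Dataset,
    ModelEvaluationError,
    ModelSpec,
    ParameterVector,
    first_order_sensitivities,
    residuals,
)

_PENALTY = 1e12  # stands in for "objective undefined here" inside optimizers


class FitError(RuntimeError):
    """All multistart optimizations failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class Objective:
    """An objective function theta -> real with an optional gradient.

    ``label`` distinguishes the original chi2 from the geometric surrogate;
    the surrogate may be undefined beyond the manifold boundary, in which
    case ``evaluate`` raises :class:`rncfit.geometry.BVPError`.
    """

    evaluate: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    label: str = "original"
    gradient_hessian: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None
    profile_min: Callable[[int, float], tuple[float, np.ndarray] | None] | None = None


def chi2_objective(model: ModelSpec, data: Dataset) -> Objective:
    """Original least-squares objective with gradient 2 J^T r."""

    def evaluate(theta: np.ndarray) -> float:
        r = residuals(model, theta, data)
        return float(r @ r)

    def gradient(theta: np.ndarray) -> np.ndarray:
        r = residuals(model, theta, data)
        J = first_order_sensitivities(model, theta, data)
        return 2.0 * J.T @ r

    return Objective(evaluate=evaluate, gradient=gradient, label="original")


def surrogate_objective(snapshot: GeometrySnapshot) -> Objective:
    """Surrogate objective chi2_tilde built on the frozen geometry, with its
    Gauss-Newton gradient/Hessian pair for Newton-type inner optimizers."""
    surr = SurrogateObjective(snapshot)
    return Objective(
        evaluate=surr.evaluate,
        gradient=surr.gradient,
        label="surrogate",
        gradient_hessian=surr.gradient_hessian,
        profile_min=surr.profile_min,
    )


def _safe_eval(objective: Objective) -> Callable[[np.ndarray], float]:
    def f(x: np.ndarray) -> float:
        try:
            val = objective.evaluate(x)
        except (BVPError, ModelEvaluationError):
            return _PENALTY
        return val if np.isfinite(val) else _PENALTY

    return f


def _safe_grad(objective: Objective) -> Callable[[np.ndarray], np.ndarray] | None:
    if objective.gradient is None:
        return None

    def g(x: np.ndarray) -> np.ndarray:
        try:
            out = objective.gradient(x)
        except (BVPError, ModelEvaluationError):
            return np.zeros_like(x)
        return np.where(np.isfinite(out), out, 0.0)

    return g


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    theta_hat: ParameterVector
    chi2_hat: float
    gradient_norm: float
    n_restarts_used: int
    converged: bool
    diagnostics: list = field(default_factory=list)


def fit(
    objective: Objective,
    theta0: ParameterVector,
    n_restarts: int = 5,
    seed: int = 0,
    gtol: float = 1e-10,
) -> FitResult:
    """Bounded multistart minimization (L-BFGS-B).

    The first start is theta0 itself; further starts are a seeded
    Latin-hypercube jitter of width max(|theta0_k|, 1) around theta0,
    clipped to the bounds.
    """
    lo = theta0.bounds[:, 0]
    hi = theta0.bounds[:, 1]
    box = [(None if not np.isfinite(l) else l, None if not np.isfinite(h) else h) for l, h in zip(lo, hi)]
    starts = [theta0.values.copy()]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=theta0.N, seed=seed)
        width = np.maximum(np.abs(theta0.values), 1.0)
        for u in sampler.random(n_restarts - 1):
            x = theta0.values + (2.0 * u - 1.0) * width
            starts.append(np.clip(x, lo, hi))

    f = _safe_eval(objective)
    g = _safe_grad(objective)
    best, diagnostics = None, []
    for x0 in starts:
        try:
            res = optimize.minimize(
                f,
                x0,
                jac=g,
                method="L-BFGS-B",
                bounds=box,
                options={"ftol": 1e-14, "gtol": gtol, "maxiter": 2000},
            )
        except Exception as exc:  # keep going through remaining starts
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        diagnostics.append(
            {"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success),
             "message": str(res.message)}
        )
        if res.fun < _PENALTY / 10 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("no multistart optimization converged", diagnostics)
    grad_norm = float(np.linalg.norm(np.atleast_1d(best.jac))) if best.jac is not None else math.nan
    return FitResult(
        theta_hat=theta0.with_values(best.x),
        chi2_hat=float(best.fun),
        gradient_norm=grad_norm,
        n_restarts_used=len(starts),
        converged=bool(best.success),
        diagnostics=diagnostics,
    )


def threshold(confidence_level: float, df: int = 1) -> float:
    """Delta-chi2 threshold T_{1-alpha}: the chi2_df quantile at the given
    confidence level (df = 1 for pointwise per-parameter profiles)."""
    if not 0 < confidence_level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    return float(chi2_dist.ppf(confidence_level, df))


# ---------------------------------------------------------------------------
# profile likelihood


@dataclass
class ProfileResult:
    parameter_index: int
    parameter_name: str
    grid: np.ndarray
    profile_values: np.ndarray
    nuisance_paths: np.ndarray  # (n_points, N) full parameter vectors
    chi2_hat: float
    theta_hat_i: float
    thresholds: dict[float, float]
    crossings: dict[float, tuple]
    end_status: dict[str, str]  # {'left': ..., 'right': ...}
    label: str = "original"
    parameter_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"parameter": self.parameter_name, "grid_value": self.grid,
             "profile_value": self.profile_values}
        )
        for j, name in enumerate(self.parameter_names):
            df[name] = self.nuisance_paths[:, j]
        return df

    def summary(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "parameter_index": self.parameter_index,
            "objective": self.label,
            "chi2_hat": self.chi2_hat,
            "theta_hat": self.theta_hat_i,
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
            "crossings": {
                str(k): {"lower": lo, "lower_kind": lk, "upper": hi, "upper_kind": hk}
                for k, (lo, lk, hi, hk) in self.crossings.items()
            },
            "end_status": self.end_status,
            "identifiable": {str(k): self.identifiable(k) for k in self.thresholds},
        }

    def identifiable(self, level: float) -> bool:
        lo, lk, hi, hk = self.crossings[level]
        return lk == "crossing" and hk == "crossing"

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def load_profile(csv_path, json_path) -> ProfileResult:
    df = pd.read_csv(csv_path)
    with open(json_path) as fh:
        summary = json.load(fh)
    names = [c for c in df.columns if c not in ("parameter", "grid_value", "profile_value")]
    return ProfileResult(
        parameter_index=int(summary["parameter_index"]),
        parameter_name=summary["parameter"],
        grid=df["grid_value"].to_numpy(float),
        profile_values=df["profile_value"].to_numpy(float),
        nuisance_paths=df[names].to_numpy(float),
        chi2_hat=float(summary["chi2_hat"]),
        theta_hat_i=float(summary["theta_hat"]),
        thresholds={float(k): v for k, v in summary["thresholds"].items()},
        crossings={
            float(k): (d["lower"], d["lower_kind"], d["upper"], d["upper_kind"])
            for k, d in summary["crossings"].items()
        },
        end_status=summary["end_status"],
        label=summary["objective"],
        parameter_names=names,
    )


def _newton_nuisance(
    objective: Objective,
    theta_full: np.ndarray,
    i: int,
    bounds: np.ndarray,
    max_iter: int = 25,
) -> tuple[float, np.ndarray] | None:
    """Projected Newton on the free parameters using the objective's
    gradient/Gauss-Newton-Hessian pair.  Returns None when the objective is
    undefined at the start (e.g. beyond the surrogate's manifold boundary)."""
    N = len(theta_full)
    free = np.array([j for j in range(N) if j != i])
    f_full = _safe_eval(objective)
    theta = theta_full.copy()
    fval = f_full(theta)
    if fval >= _PENALTY / 10:
        return None
    for _ in range(max_iter):
        try:
            g, H = objective.gradient_hessian(theta)
        except (BVPError, ModelEvaluationError):
            break
        gf = g[free]
        Hf = H[np.ix_(free, free)]
        Hf = Hf + 1e-10 * np.eye(len(free)) * max(1.0, np.trace(Hf) / len(free))
        try:
            d = np.linalg.solve(Hf, -gf)
        except np.linalg.LinAlgError:
            break
        improved = False
        alpha = 1.0
        while alpha > 2.0**-10:
            trial = theta.copy()
            trial[free] = np.clip(theta[free] + alpha * d, bounds[free, 0], bounds[free, 1])
            f_try = f_full(trial)
            if f_try < fval - 1e-14:
                theta, fval, improved = trial, f_try, True
                break
            alpha *= 0.5
        if not improved or abs(alpha * np.max(np.abs(d))) < 1e-12:
            break
    return fval, theta


def _minimize_nuisance(
    objective: Objective,
    theta_full: np.ndarray,
    i: int,
    bounds: np.ndarray,
    warm: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Minimize over all parameters except index i, starting from warm."""
    N = len(theta_full)
    free = [j for j in range(N) if j != i]
    if not free:
        return _safe_eval(objective)(theta_full), theta_full.copy()
    if objective.profile_min is not None:
        out = objective.profile_min(i, theta_full[i])
        if out is None:
            return _PENALTY, theta_full.copy()
        return out
    if objective.gradient_hessian is not None:
        out = _newton_nuisance(objective, theta_full, i, bounds)
        if out is None:
            return _PENALTY, theta_full.copy()
        return out

    f_full = _safe_eval(objective)
    g_full = _safe_grad(objective)

    def assemble(x: np.ndarray) -> np.ndarray:
        th = theta_full.copy()
        th[free] = x
        return th

    def f(x):
        return f_full(assemble(x))

    jac = None
    if g_full is not None:
        def jac(x):
            return g_full(assemble(x))[free]

    box = [
        (None if not np.isfinite(bounds[j, 0]) else bounds[j, 0],
         None if not np.isfinite(bounds[j, 1]) else bounds[j, 1])
        for j in free
    ]
    x0 = np.clip(warm[free], bounds[free, 0], bounds[free, 1])
    res = optimize.minimize(
        f, x0, jac=jac, method="L-BFGS-B", bounds=box,
        options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 300},
    )
    theta_out = assemble(res.x)
    return float(res.fun), theta_out


def profile_likelihood(
    objective: Objective,
    fit_result: FitResult,
    parameter_index: int,
    levels: Sequence[float] = (0.68, 0.95),
    max_steps: int = 200,
    range_factor: float = 1e6,
    init_rel_step: float = 0.02,
    overshoot: float = 1.2,
) -> ProfileResult:
    """Adaptive profile likelihood of one parameter under any objective.

    The step targets a per-step objective increase of about a tenth of the
    95% threshold and is clipped to [1e-4, 1.0] times the local parameter
    scale max(|theta_i|, 1), so flat directions are traversed geometrically
    (the profiled parameter at most doubles per step).
    """
    theta_hat = fit_result.theta_hat
    i = parameter_index
    N = theta_hat.N
    bounds = theta_hat.bounds
    thresholds = {lvl: threshold(lvl, df=1) for lvl in levels}
    T_max = max(thresholds.values())
    target_step = 0.1 * threshold(0.95, df=1)
    chi2_hat = fit_result.chi2_hat
    scale0 = max(abs(theta_hat.values[i]), 1.0)

    points = [(theta_hat.values[i], chi2_hat, theta_hat.values.copy())]
    end_status = {}
    for direction, side in ((1.0, "right"), (-1.0, "left")):
        status = "max_steps"
        theta_i = theta_hat.values[i]
        warm = theta_hat.values.copy()
        prev_warm: np.ndarray | None = None
        prev_step = 0.0
        prev_val = chi2_hat
        step = init_rel_step * scale0
        for _ in range(max_steps):
            scale = max(abs(theta_i), 1.0)
            step = float(np.clip(step, 1e-4 * scale, 1.0 * scale))
            theta_i_new = theta_i + direction * step
            hit_bound = False
            if theta_i_new <= bounds[i, 0]:
                theta_i_new, hit_bound = bounds[i, 0], True
            elif theta_i_new >= bounds[i, 1]:
                theta_i_new, hit_bound = bounds[i, 1], True
            # predictor: extrapolate the nuisance path along the canyon
            guess = warm.copy()
            if prev_warm is not None and prev_step > 0:
                guess = warm + (abs(theta_i_new - theta_i) / prev_step) * (warm - prev_warm)
                guess = np.clip(guess, bounds[:, 0], bounds[:, 1])
            full = guess.copy()
            full[i] = theta_i_new
            val, theta_opt = _minimize_nuisance(objective, full, i, bounds, full)
            if val >= _PENALTY / 10:
                status = "boundary"
                break
            points.append((theta_i_new, val, theta_opt))
            dchi = abs(val - prev_val)
            prev_warm, prev_step = warm, abs(theta_i_new - theta_i)
            theta_i, warm, prev_val = theta_i_new, theta_opt, val
            if val - chi2_hat > overshoot * T_max:
                status = "crossed"
                break
            if hit_bound:
                status = "bound"
                break
            if abs(theta_i - theta_hat.values[i]) > range_factor * scale0:
                status = "flat"
                break
            step *= float(np.clip(target_step / max(dchi, 1e-3 * target_step), 0.5, 4.0))
        end_status[side] = status

    # refine each threshold crossing by bisection so interpolated interval
    # endpoints do not inherit the coarse step of the outward walk
    for T in sorted(set(thresholds.values())):
        target_val = chi2_hat + T
        for side in ("left", "right"):
            for _ in range(8):
                points.sort(key=lambda p: p[0])
                idx = range(len(points) - 1) if side == "right" else range(len(points) - 1, 0, -1)
                bracket = None
                for j in idx:
                    a, b = (j, j + 1) if side == "right" else (j, j - 1)
                    ga, gb = points[a][0], points[b][0]
                    inner = ga >= theta_hat.values[i] if side == "right" else ga <= theta_hat.values[i]
                    if inner and points[a][1] < target_val <= points[b][1]:
                        bracket = (a, b)
                        break
                if bracket is None:
                    break
                a, b = bracket
                if abs(points[b][0] - points[a][0]) < 1e-3 * max(1.0, abs(points[a][0])) or (
                    points[b][1] - points[a][1] < 0.05 * T
                ):
                    break
                mid = 0.5 * (points[a][0] + points[b][0])
                full = points[a][2].copy()
                full[i] = mid
                val, theta_opt = _minimize_nuisance(objective, full, i, bounds, full)
                if val >= _PENALTY / 10:
                    break
                points.append((mid, val, theta_opt))

    points.sort(key=lambda p: p[0])
    grid = np.array([p[0] for p in points])
    values = np.array([p[1] for p in points])
    paths = np.array([p[2] for p in points])
    crossings = {
        lvl: _locate_crossings(
            grid, values, chi2_hat + T, theta_hat.values[i], end_status, bounds[i]
        )
        for lvl, T in thresholds.items()
    }
    return ProfileResult(
        parameter_index=i,
        parameter_name=theta_hat.names[i],
        grid=grid,
        profile_values=values,
        nuisance_paths=paths,
        chi2_hat=chi2_hat,
        theta_hat_i=float(theta_hat.values[i]),
        thresholds=thresholds,
        crossings=crossings,
        end_status=end_status,
        label=objective.label,
        parameter_names=list(theta_hat.names),
    )


def _locate_crossings(grid, values, target, center, end_status, bound_i):
    """Interpolated threshold crossings on each side of the optimum; ends
    that never cross carry a marker describing why."""
    out = []
    for side in ("left", "right"):
        if side == "left":
            idx = np.flatnonzero(grid <= center)[::-1]
        else:
            idx = np.flatnonzero(grid >= center)
        cross_val, kind = math.nan, None
        for a, b in zip(idx[:-1], idx[1:]):
            if values[a] < target <= values[b]:
                x0, x1, y0, y1 = grid[a], grid[b], values[a], values[b]
                cross_val = float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))
                kind = "crossing"
                break
        if kind is None:
            status = end_status.get(side, "max_steps")
            if status == "flat":
                cross_val, kind = (-math.inf if side == "left" else math.inf), "open"
            elif status == "bound":
                cross_val, kind = float(bound_i[0] if side == "left" else bound_i[1]), "bound"
            elif status == "boundary":
                cross_val, kind = math.nan, "boundary"
            else:
                cross_val, kind = math.nan, "undetermined"
        if side == "left":
            lower, lower_kind = cross_val, kind
        else:
            upper, upper_kind = cross_val, kind
    return (lower, lower_kind, upper, upper_kind)


@dataclass
class ConfidenceInterval:
    level: float
    lower: float
    upper: float
    lower_kind: str
    upper_kind: str

    def contains(self, x: float) -> bool:
        lo = self.lower if np.isfinite(self.lower) or self.lower == -math.inf else math.nan
        hi = self.upper if np.isfinite(self.upper) or self.upper == math.inf else math.nan
        if math.isnan(lo) or math.isnan(hi):
            return False
        return lo <= x <= hi


def confidence_interval(profile: ProfileResult, confidence_level: float) -> ConfidenceInterval:
    """Profile-likelihood confidence interval at a requested level.

    Ends that never cross the threshold in a flat direction are open
    (+/- inf); a profile stopped before the question is decided yields an
    explicit 'undetermined' marker rather than a silent finite endpoint.
    """
    if confidence_level not in profile.thresholds:
        raise ValueError(
            f"profile was not computed for level {confidence_level}; "
            f"available: {sorted(profile.thresholds)}"
        )
    lo, lk, hi, hk = profile.crossings[confidence_level]
    return ConfidenceInterval(confidence_level, lo, hi, lk, hk)


# ---------------------------------------------------------------------------
# original-vs-surrogate comparison


@dataclass
class ProfileComparison:
    parameter_name: str
    region_level: float
    max_abs_discrepancy: float
    mean_abs_discrepancy: float
    n_compared: int
    classification_agreement: dict[float, bool]
    classification: dict[float, dict[str, bool]]

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter_name,
            "region_level": self.region_level,
            "max_abs_discrepancy": self.max_abs_discrepancy,
            "mean_abs_discrepancy": self.mean_abs_discrepancy,
            "n_compared": self.n_compared,
            "classification_agreement": {
                str(k): v for k, v in self.classification_agreement.items()
            },
            "classification": {
                str(k): v for k, v in self.classification.items()
            },
        }


def compare_profiles(
    original: ProfileResult,
    surrogate: ProfileResult,
    region_level: float = 0.95,
) -> ProfileComparison:
    """Align two profiles of the same parameter and quantify agreement.

    Discrepancies are measured on the original profile's grid points inside
    its confidence region at ``region_level`` that also fall inside the
    surrogate's computed range.
    """
    if original.parameter_name != surrogate.parameter_name:
        raise ValueError("profiles refer to different parameters")
    T = threshold(region_level, df=1)
    mask = original.profile_values <= original.chi2_hat + T
    mask &= (original.grid >= surrogate.grid.min()) & (original.grid <= surrogate.grid.max())
    diffs = np.array([])
    if mask.any():
        interp = np.interp(original.grid[mask], surrogate.grid, surrogate.profile_values)
        diffs = np.abs(interp - original.profile_values[mask])
    levels = sorted(set(original.thresholds) & set(surrogate.thresholds))
    classification = {
        lvl: {"original": original.identifiable(lvl), "surrogate": surrogate.identifiable(lvl)}
        for lvl in levels
    }
    return ProfileComparison(
        parameter_name=original.parameter_name,
        region_level=region_level,
        max_abs_discrepancy=float(diffs.max()) if diffs.size else math.nan,
        mean_abs_discrepancy=float(diffs.mean()) if diffs.size else math.nan,
        n_compared=int(mask.sum()),
        classification_agreement={
            lvl: d["original"] == d["surrogate"] for lvl, d in classification.items()
        },
        classification=classification,
    )
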