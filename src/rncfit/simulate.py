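"""Seeded synthetic datasets under the Gaussian observation model.

Observations are y_D,m = y(t_m, theta_true) + eps_m with eps_m ~ N(0, sigma_m^2),
drawn from a single PCG64 generator seeded from the design seed only, so a
design regenerates its dataset bit-exactly.  The named fixtures realize the
study conditions of the three example models (a single printed datum for the
one-parameter exponential; a three-point decay with free initial amount; a
timescale-separated enzyme system; a 51-condition dose-response design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Dataset, ModelSpec, ParameterVector, builtin_model


@dataclass
class SimulationDesign:
    """A reproducible recipe for one dataset."""

    model_name: str
    theta_true: dict[str, float]
    times: list[float]
    sigma: float
    seed: int
    conditions: dict[str, dict] = field(default_factory=lambda: {"": {}})
    observables: list[str] = field(default_factory=list)  # empty = model default
    apply_noise: bool = True
    theta0: dict[str, float] | None = None  # suggested fit start

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "theta_true": self.theta_true,
            "times": list(map(float, self.times)),
            "sigma": self.sigma,
            "seed": self.seed,
            "conditions": self.conditions,
            "observables": self.observables,
            "apply_noise": self.apply_noise,
            "theta0": self.theta0,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        return cls(**d)


def model_for(design: SimulationDesign) -> ModelSpec:
    """Construct the built-in model a design refers to, wired with the
    design's conditions and observables."""
    kwargs = {}
    if design.model_name == "enzyme":
        kwargs["conditions"] = design.conditions
        if design.observables:
            kwargs["observables"] = design.observables
    return builtin_model(design.model_name, **kwargs)


def theta_true_vector(design: SimulationDesign, model: ModelSpec | None = None) -> ParameterVector:
    model = model or model_for(design)
    return model.parameter_vector([design.theta_true[p] for p in model.param_names])


def simulate(design: SimulationDesign) -> Dataset:
    """Draw one dataset from the design's observation model.

    A zero design sigma yields noise-free observations, recorded with unit
    weights (datasets require strictly positive standard deviations).
    """
    model = model_for(design)
    sigma_rec = design.sigma if design.sigma > 0 else 1.0
    theta = theta_true_vector(design, model)
    rng = np.random.default_rng(design.seed)
    rows = []
    observables = design.observables or [""]
    for cond_label in design.conditions:
        for obs in observables:
            y = model.predict(np.asarray(design.times, float), theta.values, cond_label, obs or None)
            y = np.atleast_1d(y)
            eps = rng.normal(0.0, design.sigma, size=len(design.times)) if (
                design.apply_noise and design.sigma > 0
            ) else np.zeros(len(design.times))
            for t, yv, e in zip(design.times, y, eps):
                rows.append((t, yv + e, sigma_rec, cond_label, obs))
    return Dataset(
        pd.DataFrame(rows, columns=["time", "value", "sigma", "condition", "observable"])
    )


_FIXTURES = {}


def _fixture(fn):
    _FIXTURES[fn.__name__] = fn
    return fn


@_fixture
def model1_paper() -> SimulationDesign:
    # the single printed datum y_D = 1 at t = 1 with sigma = 1, noise-free
    return SimulationDesign(
        model_name="exp_fixed",
        theta_true={"k1": 0.0},
        times=[1.0],
        sigma=1.0,
        seed=10,
        apply_noise=False,
        theta0={"k1": 1.0},
    )


@_fixture
def model2_default() -> SimulationDesign:
    # three observations of A0 exp(-k1 t): enough to fix the optimum but not
    # to close the coupled A0-k1 canyon toward large values
    return SimulationDesign(
        model_name="exp_decay",
        theta_true={"k1": 1.0, "A0": 1.0},
        times=[1.0, 2.0, 3.0],
        sigma=0.02,
        seed=20,
        theta0={"k1": 0.5, "A0": 0.5},
    )


@_fixture
def model3_default() -> SimulationDesign:
    # timescale separation k1, k2 >> k3: binding/dissociation equilibrate
    # fast, so only their ratio is well constrained; the single early sample
    # catches the tail of the binding transient, pinning a unique interior
    # optimum while leaving k1, k2 free to run toward +inf below threshold
    return SimulationDesign(
        model_name="enzyme",
        theta_true={"k1": 10.0, "k2": 10.0, "k3": 0.1, "S0": 1.0},
        times=[0.12, 1.0, 2.0, 5.0, 10.0, 20.0, 35.0, 50.0, 75.0, 100.0],
        sigma=0.02,
        seed=34,
        conditions={"c0": {"E0": 0.4}},
        observables=["S", "P"],
        theta0={"k1": 5.0, "k2": 5.0, "k3": 0.2, "S0": 1.5},
    )


@_fixture
def model3_dose_response() -> SimulationDesign:
    # 51 initial enzyme concentrations, product read out at two times each
    doses = np.logspace(-2, 0.5, 51)
    return SimulationDesign(
        model_name="enzyme",
        theta_true={"k1": 10.0, "k2": 10.0, "k3": 0.1, "S0": 1.0},
        times=[10.0, 50.0],
        sigma=0.02,
        seed=31,
        conditions={f"E0_{i:02d}": {"E0": float(d)} for i, d in enumerate(doses)},
        observables=["P"],
        theta0={"k1": 5.0, "k2": 5.0, "k3": 0.2, "S0": 1.5},
    )


def fixture(name: str) -> tuple[SimulationDesign, Dataset]:
    """Return a named frozen design together with its simulated dataset."""
    try:
        design = _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture '{name}'; available: {sorted(_FIXTURES)}"
        ) from None
    return design, simulate(design)


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)
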