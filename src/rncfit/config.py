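"""Run configuration: YAML parsing, defaults, and model construction."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import Dataset, ModelSpec, ParameterVector, builtin_model


class ConfigError(ValueError):
    """The run configuration is invalid or incomplete."""


_DEFAULTS = {
    "fit": {"n_restarts": 5, "seed": 0},
    "geometry": {"fd_step": 1e-4, "theta_bound": 1e6, "xi_bound": 1e12, "bvp_tol": 1e-8},
    "profile": {"levels": [0.68, 0.95], "max_steps": 200, "range_factor": 1e6},
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one analysis run."""

    model: dict
    data: dict
    fit: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    output: str = "rncfit_out"

    def __post_init__(self) -> None:
        for section in ("fit", "geometry", "profile"):
            merged = dict(_DEFAULTS[section])
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)
        if not isinstance(self.model, dict) or "name" not in self.model:
            raise ConfigError("config must provide model.name")
        if not isinstance(self.data, dict) or not ({"path", "fixture"} & set(self.data)):
            raise ConfigError("config must provide data.path or data.fixture")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        try:
            return cls(
                model=raw.get("model", {}),
                data=raw.get("data", {}),
                fit=raw.get("fit", {}),
                geometry=raw.get("geometry", {}),
                profile=raw.get("profile", {}),
                output=raw.get("output", "rncfit_out"),
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def resolved(self) -> dict:
        return {
            "model": self.model,
            "data": self.data,
            "fit": self.fit,
            "geometry": self.geometry,
            "profile": self.profile,
            "output": self.output,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)


def build_model(cfg: RunConfig) -> tuple[ModelSpec, ParameterVector]:
    """Instantiate the configured model and its initial parameter vector."""
    spec = cfg.model
    kwargs = {}
    if "n" in spec:
        kwargs["n"] = spec["n"]
    if "conditions" in spec:
        kwargs["conditions"] = spec["conditions"]
    if "observables" in spec:
        kwargs["observables"] = spec["observables"]
    if "basis" in spec:
        # basis entries are (coefficient-free) monomial powers of t
        powers = [float(p) for p in spec["basis"]]
        kwargs["basis"] = [
            (lambda t, p=p: np.asarray(t, dtype=float) ** p) for p in powers
        ]
    try:
        model = builtin_model(spec["name"], **kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    params = spec.get("parameters", {})
    values, bounds = [], []
    for name in model.param_names:
        entry = params.get(name, {})
        values.append(float(entry.get("init", 1.0)))
        default = model.default_bounds[model.param_names.index(name)]
        raw_bounds = entry.get("bounds", default)
        bounds.append([_as_float(raw_bounds[0]), _as_float(raw_bounds[1])])
    try:
        theta0 = ParameterVector(np.asarray(values), model.param_names, np.asarray(bounds))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return model, theta0


def _as_float(x) -> float:
    return float(x)  # accepts "inf"/"-inf" strings from YAML as well


def dataset_sha256(dataset: Dataset) -> str:
    csv_bytes = dataset.frame.to_csv(index=False).encode()
    return hashlib.sha256(csv_bytes).hexdigest()


def load_dataset(cfg: RunConfig, base_dir: Path | None = None) -> Dataset:
    from .simulate import fixture  # local import to avoid a cycle

    if "fixture" in cfg.data:
        _, ds = fixture(cfg.data["fixture"])
        return ds
    path = Path(cfg.data["path"])
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    if not path.exists():
        raise ConfigError(f"dataset file not found: {path}")
    return Dataset.from_csv(path)
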