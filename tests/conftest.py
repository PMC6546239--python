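import numpy as np
import pytest

import rncfit as rf


@pytest.fixture(scope="session")
def model1():
    return rf.builtin_model("exp_fixed")


@pytest.fixture(scope="session")
def model1_data():
    _, ds = rf.fixture("model1_paper")
    return ds


@pytest.fixture(scope="session")
def model1_snapshot(model1, model1_data):
    """Geometry of the one-parameter exponential at its optimum k1 = 0."""
    theta_hat = model1.parameter_vector([0.0])
    return rf.compute_geometry(model1, theta_hat, model1_data)


@pytest.fixture(scope="session")
def linear2_model():
    return rf.builtin_model("linear", basis=[lambda t: np.ones_like(t), lambda t: t])


@pytest.fixture(scope="session")
def linear2_data(linear2_model):
    t = np.array([0.0, 1.0, 2.0, 3.0])
    theta_true = np.array([1.0, -0.5])
    y = linear2_model.predictions(theta_true, rf.Dataset.from_arrays(t, np.zeros_like(t), 1.0))
    return rf.Dataset.from_arrays(t, y, 0.5)


@pytest.fixture(scope="session")
def linear2_snapshot(linear2_model, linear2_data):
    obj = rf.chi2_objective(linear2_model, linear2_data)
    res = rf.fit(obj, linear2_model.parameter_vector([0.0, 0.0]), n_restarts=1, seed=0)
    return rf.compute_geometry(linear2_model, res.theta_hat, linear2_data)


@pytest.fixture(scope="session")
def model2_fit():
    """Fitted three-point exponential-decay fixture (model, data, fit, snapshot)."""
    design, ds = rf.fixture("model2_default")
    model = rf.model_for(design)
    obj = rf.chi2_objective(model, ds)
    theta0 = model.parameter_vector([design.theta0[p] for p in model.param_names])
    res = rf.fit(obj, theta0, n_restarts=3, seed=0)
    snap = rf.compute_geometry(model, res.theta_hat, ds)
    return model, ds, res, snap
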