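"""Scanning for model-manifold boundaries with geodesics.

For the single-datum exponential model the manifold is a half-line: the
prediction exp(-k1) covers (0, inf), so chi2 is bounded as k1 -> +inf
(boundary at arc length 1 in RNC) and unbounded as k1 -> -inf.  A linear
model, by contrast, has vanishing Christoffel symbols, straight geodesics,
and no boundary in any direction.
"""

import math

import numpy as np

import rncfit as rf

design, data = rf.fixture("model1_paper")
model = rf.model_for(design)
result = rf.fit(rf.chi2_objective(model, data), model.parameter_vector([1.0]), n_restarts=2, seed=0)
snapshot = rf.compute_geometry(model, result.theta_hat, data)

for direction in (+1.0, -1.0):
    r = rf.boundary_scan(snapshot, [direction], v_max=1e4)
    r_str = f"boundary at arc length {r:.6f}" if math.isfinite(r) else "unbounded"
    print(f"exp(-k1 t), direction {direction:+.0f}: {r_str}")
print("  (the +k1 boundary is the zero-prediction limit: chi2 plateaus at 1)")

linear = rf.builtin_model("linear", basis=[lambda t: np.ones_like(t), lambda t: t])
t = np.array([0.0, 1.0, 2.0, 3.0])
lin_data = rf.Dataset.from_arrays(t, 1.0 - 0.5 * t, 0.5)
lin_fit = rf.fit(
    rf.chi2_objective(linear, lin_data), linear.parameter_vector([0.0, 0.0]), n_restarts=1, seed=0
)
lin_snap = rf.compute_geometry(linear, lin_fit.theta_hat, lin_data)

print("\nlinear model (Gamma = 0):")
for d in ([1.0, 0.0], [0.0, 1.0], [1.0, -1.0]):
    r = rf.boundary_scan(lin_snap, d, v_max=100.0)
    print(f"  direction {d}: {'unbounded' if math.isinf(r) else r}")
print("  (flat manifold: geodesics are straight lines, chi2 grows without bound)")
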