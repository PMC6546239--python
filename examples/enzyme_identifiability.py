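"""Enzyme kinetics: practical non-identifiability from local geometry.

Mass-action enzyme kinetics (E + S <-> C -> E + P) with timescale
separation k1, k2 >> k3: binding equilibrates fast, so the data constrain
essentially only the ratio k2/k1.  Profiles of k1 and k2 stay below the
68% threshold toward large values (practically non-identifiable, open
confidence intervals), while k3 and the initial substrate S0 are
identifiable.  The geometric surrogate — built from one evaluation of
second-order sensitivities at the optimum — reproduces this classification
without further ODE solves.
"""

import numpy as np

import rncfit as rf

design, data = rf.fixture("model3_default")
model = rf.model_for(design)
objective = rf.chi2_objective(model, data)
theta0 = model.parameter_vector([design.theta0[p] for p in model.param_names])
result = rf.fit(objective, theta0, n_restarts=2, seed=1)
snapshot = rf.compute_geometry(model, result.theta_hat, data)

print(f"theta_hat = { {k: round(v, 4) for k, v in result.theta_hat.as_dict().items()} }")
print(f"chi2_hat = {result.chi2_hat:.3f} on {data.M} observations")
print(f"metric condition number = {snapshot.metric.condition_number:.2e}")
print(f"68% threshold (df=1): {rf.threshold(0.68):.3f}\n")

# profile one practically non-identifiable parameter (k1) and one
# identifiable parameter (k3) under each objective; the full four-parameter
# comparison runs the same way (see the test suite)
for label, obj in (("original", objective), ("surrogate", rf.surrogate_objective(snapshot))):
    print(f"--- {label} objective ---")
    for name in ("k1", "k3"):
        prof = rf.profile_likelihood(obj, result, model.param_names.index(name), levels=(0.68,))
        lo, lk, hi, hk = prof.crossings[0.68]
        verdict = "identifiable" if prof.identifiable(0.68) else "practically NON-identifiable"
        hi_str = f"{hi:.4g}" if np.isfinite(hi) else hk
        lo_str = f"{lo:.4g}" if np.isfinite(lo) else lk
        print(f"  {name:3s}: 68% interval [{lo_str}, {hi_str}]  -> {verdict}")
    print()

print("k1 runs open-ended toward large values (only k2/k1 is constrained once")
print("binding is in quasi-equilibrium); k3 has a finite interval. The surrogate")
print("reaches the same classification from the frozen local geometry alone.")
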