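"""Detect differentially variable probes with the model-based detector.

Simulates a probe-by-sample expression matrix from the three-cluster
generating model (310 over-variable, 580 equal-variance, 110 under-variable
probes; 50 cases, 50 controls), fits the constrained mixture by EM and
assigns every probe to the OV/EV/UV cluster with the largest posterior
probability.
"""

import numpy as np

from dvclust import FitConfig, ScenarioConfig, detect_dv, jaccard_index, simulate_dataset

data, truth = simulate_dataset(ScenarioConfig(scenario="SimI", G=1000, seed=1))
call, result = detect_dv(data, FitConfig(seed=1))

print(f"EM converged after {result.n_iter} iterations, log-likelihood {result.loglik:.1f}")
print(f"estimated mixing proportions pi = {np.round(result.model.pi, 3)}  (truth: 0.31 0.58 0.11)")
for c in result.model.clusters:
    print(
        f"  {c.kind}: case sigma^2 = {c.sigma2_c:.2f}, control sigma^2 = {c.sigma2_n:.2f}, "
        f"rho = ({c.rho_c:.2f}, {c.rho_n:.2f})"
    )
for kind in ("OV", "EV", "UV"):
    print(f"detected {int(np.sum(call.labels == kind)):4d} {kind} probes")
print(f"pair-counting Jaccard index vs truth: {jaccard_index(truth.labels, call.labels):.3f}")
print("(1.0 would be perfect agreement between detected and true cluster memberships)")
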