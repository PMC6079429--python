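"""How heavy-tailed data degrade the normal-mixture detector.

The heavy-tail scenario keeps the generating means and covariance
structure but draws each probe vector from a multivariate t distribution
with 3 degrees of freedom, violating the normality assumption of every
cluster.  Agreement with the truth collapses (median Jaccard well below
the near-perfect values seen on normal data).
"""

import warnings

import numpy as np

from dvclust import FitConfig, ScenarioConfig, detect_dv, jaccard_index, simulate_dataset

for scenario in ("SimI", "SimII"):
    js = []
    for seed in range(5):
        data, truth = simulate_dataset(ScenarioConfig(scenario=scenario, G=1000, seed=50 + seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            call, _ = detect_dv(data, FitConfig(seed=seed))
        js.append(jaccard_index(truth.labels, call.labels))
    tag = "normal mixture" if scenario == "SimI" else "multivariate t, df=3"
    print(f"{scenario} ({tag}): Jaccard per replicate {np.round(js, 3)}, "
          f"median {np.median(js):.3f}")

print("\nUnder heavy tails the fitted normal clusters absorb outlying probes,")
print("so detected memberships agree far less with the truth — the known")
print("robustness limit of the normality assumption.")
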