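"""Fit the spatiotemporal Poisson model and recover covariate effects.

Simulates a study-scale panel (84 areas x 5 years, ~2630 events) with
known covariate relative risks — 1.03 per % renters, 0.97 per % white,
0.90 per % crowded housing — then fits the BYM model by MCMC and
prints the posterior relative risks next to the generating truth.
"""

import numpy as np

import arealrisk as ar

lattice, cov, panel, truth = ar.paper_scale_scenario(seed=3)
panel = ar.sir(ar.expected_counts(panel))
print(f"simulated {panel['Y'].sum()} events over {len(panel)} area-year cells")

spec = ar.ModelSpec(
    spatial_family="bym",
    interaction=True,
    covariates=("renters", "white", "crowded"),
)
post = ar.fit(panel, cov, lattice, spec, chains=1, iters=2000, warmup=1500,
              seed=1)
print("max split R-hat:", round(post.diagnostics["max_rhat"], 3))

rr = ar.rr_covariates(post)
rr["truth"] = [np.exp(truth.beta[c]) for c in rr["covariate"]]
print("\nposterior relative risks (per unit of each covariate):")
print(rr.round(3).to_string(index=False))
print("\nRR > 1 means the covariate raises incidence risk; each interval"
      "\nshould usually cover the generating truth in the last column.")
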