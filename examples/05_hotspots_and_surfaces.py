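"""Hotspot probabilities and choropleth-ready surfaces.

Fits a small polygon lattice, computes the model-based relative-risk
surface and the exceedance probability P(RR > 1 | data) per area-year,
and exports everything as a GeoJSON whose per-feature properties are
ready to style as maps.
"""

import json

from shapely.geometry import box

import arealrisk as ar

# a 4x5 map of unit-square "zip codes"
polys = {f"z{i}{j}": box(j, i, j + 1, i + 1) for i in range(4) for j in range(5)}
lattice = ar.build_adjacency(polys, contiguity="queen")

years = [2015, 2016]
cov = ar.simulate_covariates(lattice, years, seed=4)
panel, truth = ar.simulate_counts(
    lattice, cov, ar.TruthSpec(target_total=800.0), seed=5
)
panel = ar.sir(ar.expected_counts(panel))

spec = ar.ModelSpec(spatial_family="bym", interaction=True,
                    covariates=("renters",))
post = ar.fit(panel, cov, lattice, spec, chains=1, iters=800, warmup=800,
              seed=6)

fitted = ar.fitted_rr(post)
exc = ar.exceedance(post, rr_threshold=1.0)
likely_hot = exc[exc["P_exceed"] > 0.8]
print(f"{len(likely_hot)} of {len(exc)} area-years have P(RR > 1) > 0.8:")
print(likely_hot.round(3).head(6).to_string(index=False))

gj = ar.export_surfaces(panel, fitted, exc, polys)
first = gj["features"][0]["properties"]
print("\nper-feature GeoJSON properties (first area):")
print(json.dumps(first, indent=2))
print("\nSIR_<year> is the raw ratio, RR_<year> its model-smoothed"
      "\ncounterpart, PexcRR1_<year> the posterior hotspot probability.")
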