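"""From event records to standardized incidence ratios.

Builds an event fixture matching the study's yearly totals
(449/487/473/555/666 incidents, 2015-2019), aggregates it to an
area x year panel, computes expected counts by internal
standardization and the SIR per cell.  An SIR above 1 marks a
candidate hot spot (more incidents than the area's population share
predicts).
"""

import arealrisk as ar
from arealrisk.synthetic import HOUSTON_YEARLY_TOTALS

lat = ar.grid_lattice(7, 12)  # 84 areas, the study's size
events = ar.simulate_events(HOUSTON_YEARLY_TOTALS, lat.area_ids, seed=0)

prof = ar.temporal_profile(events, "year")
print("events per year:")
print(prof.to_string())
print("total:", prof.sum(), "(sums the yearly study totals)")

panel, excluded = ar.aggregate_events(events, lat, sorted(HOUSTON_YEARLY_TOTALS))
print(f"\naggregated to {len(panel)} area-year cells; {excluded} excluded")

cov = ar.simulate_covariates(lat, sorted(HOUSTON_YEARLY_TOTALS), seed=1)
panel = panel.merge(
    cov[["area_id", "year", "population"]].rename(columns={"population": "N"}),
    on=["area_id", "year"],
)
panel = ar.sir(ar.expected_counts(panel))
print("\nsum(E) == sum(Y):", round(panel["E"].sum(), 6), "==", panel["Y"].sum())
hot = (panel["SIR"] > 1).sum()
print(f"cells with SIR > 1 (raw hot spots): {hot} of {len(panel)}")
print(panel.head(3).round(3).to_string(index=False))
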