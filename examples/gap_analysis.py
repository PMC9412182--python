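"""Reserve effectiveness and conservation gaps of the final hotspots.

Hotspot counties not overlapping a reserve class are conservation gaps.
For each class (NNR, PNR, either) the hotspot set is partitioned and
species coverage is tabulated for both sides, plus the priority-group
composition (threatened / endemic excluding threatened / remaining) of
the combined gap.
"""

import phylohotspots as ph

ds = ph.simulate_dataset(seed=2)
res = ph.run_pipeline(ds.occ, ds.phylo)
hotspots = res.final_hotspots
print(f"final hotspots (top 10% of area): {len(hotspots)} counties")

for rep in res.gap_reports:
    gap_cov = rep.gap_coverage.set_index("group")
    print(f"{rep.reserve_class}: {len(rep.protected_counties)} protected "
          f"({rep.percent_protected}%), {len(rep.gap_counties)} gap counties "
          f"({rep.percent_gap}%) holding "
          f"{gap_cov.loc['all', 'percent_of_group']}% of species")

both = next(r for r in res.gap_reports if r.reserve_class == "NNR_or_PNR")
comp = ph.composition_breakdown(both.gap_counties, ds.occ)
print(f"\ncomposition of the NNR-or-PNR gap: "
      f"{comp.counts['threatened']} threatened "
      f"({comp.percents['threatened']}%), "
      f"{comp.counts['endemic_excl_threatened']} endemic non-threatened "
      f"({comp.percents['endemic_excl_threatened']}%), "
      f"{comp.counts['remaining']} remaining")
missed = ds.truth.reserve_gap_centers & hotspots.county_set
print(f"planted reserve-gap centers surfacing as gaps: {sorted(missed)}")
# High threatened/endemic percentages in the gap columns are the signal
# that new reserves are needed exactly where the hotspots are unprotected.
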