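"""End-to-end hotspot analysis.

Runs the three hotspot algorithms (species richness, greedy
complementarity, spatial phylogenetics), standardizes every pattern,
cuts per-algorithm hotspot sets at the largest configured area fraction,
integrates them into the final 5/10/17% hotspot ranking, and produces
coverage, correlation, gap and composition tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import metrics
from .assess import (GapReport, composition_long_table, correlation_matrix,
                     effectiveness_and_gaps)
from .complementarity import (ComplementaritySelection, complementarity_pattern,
                              greedy_complementary_cover)
from .io import AnalysisConfig, OccurrenceTable, PatternVector, Phylogeny
from .prioritize import (HotspotSet, IntegratedHotspots, algorithm_hotspots,
                         coverage_summary, integrate_hotspots)

#: subsets driving the richness and complementarity algorithms
ALGORITHM_SUBSETS = ("seed", "endemic", "threatened")


@dataclass(frozen=True)
class PipelineResult:
    patterns: dict[str, PatternVector]          # standardized, by name
    comp_selections: dict[str, ComplementaritySelection]
    richness_set: HotspotSet
    comp_set: HotspotSet
    phylo_set: HotspotSet
    integrated: IntegratedHotspots
    coverage: dict[float, pd.DataFrame]
    gap_reports: list[GapReport]
    correlations: pd.DataFrame
    final_fraction: float

    @property
    def final_hotspots(self) -> HotspotSet:
        return self.integrated.final_sets[self.final_fraction]

    def tables(self, occ: OccurrenceTable) -> dict[str, pd.DataFrame]:
        """All results as named tables for :func:`phylohotspots.io.write_report`."""
        pat = pd.DataFrame({"county_id": list(occ.counties.index)})
        for name, p in self.patterns.items():
            pat[name] = p.values.to_numpy()
            pat[f"{name}_std"] = p.standardized.to_numpy()
        member = pd.DataFrame({"county_id": list(occ.counties.index)})
        for f, hs in self.integrated.final_sets.items():
            member[f"top{int(round(100 * f))}"] = member["county_id"].isin(
                hs.county_set)
        coverage = pd.concat(
            [df.assign(fraction=f) for f, df in self.coverage.items()],
            ignore_index=True)
        gaps = pd.DataFrame([
            {"reserve_class": g.reserve_class,
             "protected_counties": len(g.protected_counties),
             "gap_counties": len(g.gap_counties),
             "percent_protected": g.percent_protected,
             "percent_gap": g.percent_gap}
            for g in self.gap_reports])
        comp_trace = pd.concat(
            [sel.as_frame().assign(subset=name)
             for name, sel in self.comp_selections.items()],
            ignore_index=True)
        named_sets = {"hotspots": self.final_hotspots}
        for g in self.gap_reports:
            named_sets[f"{g.reserve_class}_protected"] = g.protected_counties
            named_sets[f"{g.reserve_class}_gap"] = g.gap_counties
        return {
            "patterns": pat,
            "hotspot_membership": member,
            "coverage": coverage,
            "gap_summary": gaps,
            "complementarity_trace": comp_trace,
            "correlations": self.correlations,
            "composition": composition_long_table(
                named_sets, occ) if len(self.final_hotspots) else pd.DataFrame(),
        }


def compute_patterns(occ: OccurrenceTable, phylo: Phylogeny,
                     config: AnalysisConfig | None = None
                     ) -> tuple[dict[str, PatternVector],
                                dict[str, ComplementaritySelection]]:
    """All standardized distribution patterns plus the greedy traces."""
    config = config or AnalysisConfig()
    pats: dict[str, PatternVector] = {}
    for name in ("seed", "angiosperm", "gymnosperm", "endemic", "threatened"):
        sub = metrics.STANDARD_SUBSETS[name]
        pats[f"{name}_richness"] = metrics.species_richness(occ, sub)
    selections: dict[str, ComplementaritySelection] = {}
    for name in ALGORITHM_SUBSETS:
        sel = greedy_complementary_cover(occ, metrics.STANDARD_SUBSETS[name])
        selections[name] = sel
        pats[f"comp_{name}"] = complementarity_pattern(sel, occ, f"comp_{name}")
    pats["PD"] = metrics.pd_pattern(phylo, occ,
                                    include_root=config.pd_include_root)
    pats["PE"] = metrics.phylogenetic_endemism(phylo, occ)
    pats["WE"] = metrics.weighted_endemism(occ)
    pats = {k: metrics.standardize(v) for k, v in pats.items()}
    combined = metrics.phylo_combined_score(pats["PD"], pats["PE"], pats["WE"])
    pats["phylo_combined"] = metrics.standardize(combined)
    return pats, selections


def run_pipeline(occ: OccurrenceTable, phylo: Phylogeny,
                 config: AnalysisConfig | None = None) -> PipelineResult:
    """Full analysis: patterns -> per-algorithm hotspots -> integration ->
    coverage, correlation and reserve-gap reports."""
    config = config or AnalysisConfig()
    pats, selections = compute_patterns(occ, phylo, config)
    counties = occ.counties
    cut = max(config.area_fractions)

    richness_set = algorithm_hotspots(
        [pats[f"{n}_richness"] for n in ALGORITHM_SUBSETS],
        counties, cut, "richness")
    comp_set = algorithm_hotspots(
        [pats[f"comp_{n}"] for n in ALGORITHM_SUBSETS],
        counties, cut, "complementary")
    phylo_set = algorithm_hotspots(
        [pats[n] for n in ("PD", "PE", "WE")], counties, cut, "spatial_phylo")

    nine = ([pats[f"{n}_richness"] for n in ALGORITHM_SUBSETS]
            + [pats[f"comp_{n}"] for n in ALGORITHM_SUBSETS]
            + [pats[n] for n in ("PD", "PE", "WE")])
    integrated = integrate_hotspots(richness_set, comp_set, phylo_set, nine,
                                    counties, config)
    coverage = {f: coverage_summary(hs, occ, config.percent_decimals)
                for f, hs in integrated.final_sets.items()}

    final_fraction = (0.10 if 0.10 in config.area_fractions
                      else max(config.area_fractions))
    gap_reports = effectiveness_and_gaps(
        integrated.final_sets[final_fraction], counties, occ,
        config.percent_decimals)
    corr_names = [f"{n}_richness" for n in
                  ("seed", "angiosperm", "gymnosperm", "endemic", "threatened")]
    corr_names += [f"comp_{n}" for n in ALGORITHM_SUBSETS] + ["PD", "PE", "WE"]
    correlations = correlation_matrix([pats[n] for n in corr_names], counties,
                                      zero_fill=config.zero_fill)
    return PipelineResult(pats, selections, richness_set, comp_set, phylo_set,
                          integrated, coverage, gap_reports, correlations,
                          final_fraction)
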