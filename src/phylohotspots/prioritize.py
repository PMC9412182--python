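"""Top-area hotspot selection and multi-algorithm integration.

"Top X%" means cumulative land-area fraction, not county count: counties
are ranked by score (descending, ties broken by county_id), and the
ranked prefix whose cumulative area fraction of the total study area is
closest to the target is selected. Zero-score counties are never
selected. The integrated 5/10/17% hotspots are built from counties
flagged by at least ``min_algorithms`` of the three per-algorithm
hotspot sets, re-ranked by the sum of nine standardized patterns
(3 richness + 3 complementarity + PD + PE + WE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnalysisConfig, OccurrenceTable, PatternVector
from .assess import percent
from .metrics import STANDARD_SUBSETS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HotspotSet:
    """An ordered county selection cut at a target area fraction."""

    label: str
    selected: tuple[str, ...]
    area_fraction_target: float
    area_fraction_realized: float
    scores: pd.Series                      # full ranking scores (county_id -> score)

    def __contains__(self, county_id: str) -> bool:
        return county_id in set(self.selected)

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def county_set(self) -> frozenset[str]:
        return frozenset(self.selected)


@dataclass(frozen=True)
class IntegratedHotspots:
    union_set: frozenset[str]
    candidate_set: frozenset[str]
    final_sets: dict[float, HotspotSet]
    scores: pd.Series                      # 9-pattern sum over candidates


def _rank(scores: pd.Series) -> pd.Series:
    """Descending score, ties by county_id ascending; zero scores dropped."""
    s = scores[scores > 0]
    order = sorted(s.index, key=lambda c: (-s[c], c))
    return s.loc[order]


def _select_prefix(scores: pd.Series, counties: pd.DataFrame, fraction: float,
                   label: str) -> HotspotSet:
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    ranked = _rank(scores)
    total_area = float(counties["area_km2"].sum())
    if ranked.empty:
        logger.warning("all scores are zero for %r; empty hotspot set", label)
        return HotspotSet(label, (), fraction, 0.0, scores)
    areas = counties.loc[ranked.index, "area_km2"].to_numpy(dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(areas)]) / total_area
    k = int(np.argmin(np.abs(cum - fraction)))   # ties -> smaller prefix
    return HotspotSet(label, tuple(ranked.index[:k]), fraction, float(cum[k]),
                      scores)


def select_top_by_area(pattern: PatternVector, counties: pd.DataFrame,
                       fraction: float, label: str | None = None) -> HotspotSet:
    """Cut a standardized pattern at a cumulative-area-fraction threshold."""
    if not pattern.is_standardized:
        raise ValueError(f"pattern {pattern.name!r} must be standardized first")
    scores = pattern.standardized.reindex(counties.index, fill_value=0.0)
    return _select_prefix(scores, counties, fraction, label or pattern.name)


def algorithm_hotspots(patterns: list[PatternVector], counties: pd.DataFrame,
                       fraction: float, label: str) -> HotspotSet:
    """Hotspots of one algorithm: counties ranked by the summed
    standardized patterns of that algorithm, cut at the area fraction."""
    if not patterns:
        raise ValueError("pattern list is empty")
    for p in patterns:
        if not p.is_standardized:
            raise ValueError(f"pattern {p.name!r} must be standardized first")
    scores = sum(p.standardized.reindex(counties.index, fill_value=0.0)
                 for p in patterns)
    return _select_prefix(scores, counties, fraction, label)


def integrate_hotspots(richness_set: HotspotSet, comp_set: HotspotSet,
                       phylo_set: HotspotSet,
                       all_patterns: list[PatternVector],
                       counties: pd.DataFrame,
                       config: AnalysisConfig | None = None) -> IntegratedHotspots:
    """Overlap the three per-algorithm hotspot sets and rank the overlap.

    Counties present in >= min_algorithms sets form the candidate pool;
    within it, counties are ranked by the summed standardized score of
    ``all_patterns`` (the nine pipeline patterns) and the configured area
    fractions are cut against TOTAL study area.
    """
    config = config or AnalysisConfig()
    sets = [richness_set.county_set, comp_set.county_set, phylo_set.county_set]
    union: frozenset[str] = frozenset().union(*sets)
    membership = pd.Series(0, index=counties.index)
    for s in sets:
        membership[list(s)] += 1
    candidates = frozenset(membership.index[membership >= config.min_algorithms])
    if not candidates:
        raise ValueError(
            "empty candidate set (set sizes: "
            f"richness={len(sets[0])}, complementary={len(sets[1])}, "
            f"phylo={len(sets[2])})")
    for p in all_patterns:
        if not p.is_standardized:
            raise ValueError(f"pattern {p.name!r} must be standardized first")
    total = sum(p.standardized.reindex(counties.index, fill_value=0.0)
                for p in all_patterns)
    cand_scores = total.where(total.index.isin(candidates), 0.0)
    final = {
        f: _select_prefix(cand_scores, counties, f, f"integrated_top{f:g}")
        for f in config.area_fractions
    }
    return IntegratedHotspots(union, candidates, final, total.loc[sorted(candidates)])


def coverage_summary(county_set, occ: OccurrenceTable,
                     decimals: int = 2) -> pd.DataFrame:
    """Species coverage of a county set per taxon group.

    One row per group in {all, angiosperm, gymnosperm, endemic,
    threatened}: the number of recorded group taxa with at least one
    record inside the set and its percentage of all recorded group taxa.
    """
    if isinstance(county_set, HotspotSet):
        county_set = county_set.selected
    inside = set(occ.taxa_in(county_set))
    recorded = set(occ.recorded_taxa)
    rows = []
    for gname, subset in [("all", STANDARD_SUBSETS["seed"]),
                          ("angiosperm", STANDARD_SUBSETS["angiosperm"]),
                          ("gymnosperm", STANDARD_SUBSETS["gymnosperm"]),
                          ("endemic", STANDARD_SUBSETS["endemic"]),
                          ("threatened", STANDARD_SUBSETS["threatened"])]:
        members = set(subset.select(occ)) & recorded
        count = len(members & inside)
        pct = percent(count, len(members), decimals) if members else 0.0
        rows.append((gname, count, pct))
    return pd.DataFrame(rows, columns=["group", "species_count", "percent_of_group"])
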