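"""Pattern correlation, reserve effectiveness/gap accounting, and
priority-group composition tables.

Pearson correlations run on the aligned standardized vectors with
counties lacking records zero-filled; |r| is binned into the
conventional strength classes (>=0.8 very strong, 0.6-0.8 strong,
0.4-0.6 moderate, 0.2-0.4 weak, <0.2 very weak or none). A county counts
as protected by a reserve class when its coverage flag is true — partial
overlap is enough, which overestimates effectiveness; the limitation is
inherent to county-granular data and is reported as-is.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io import OccurrenceTable, PatternVector

STRENGTH_BINS = (
    (0.8, "very_strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
    (0.0, "very_weak_or_none"),
)


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP)
    return float(val)


def strength_of(r: float) -> str | None:
    """Map |r| to its correlation-strength class; None for NaN."""
    if r is None or math.isnan(r):
        return None
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValueError("|r| cannot exceed 1")
    for lo, label in STRENGTH_BINS:
        if a >= lo:
            return label
    return "very_weak_or_none"


@dataclass(frozen=True)
class CorrelationResult:
    pattern_a: str
    pattern_b: str
    r: float
    p_value: float
    strength: str | None


def _aligned(a: PatternVector, b: PatternVector, counties: pd.DataFrame,
             zero_fill: bool) -> tuple[np.ndarray, np.ndarray]:
    va = a.standardized if a.is_standardized else a.values
    vb = b.standardized if b.is_standardized else b.values
    if zero_fill:
        va = va.reindex(counties.index, fill_value=0.0)
        vb = vb.reindex(counties.index, fill_value=0.0)
    else:
        common = va.index.intersection(vb.index)
        va, vb = va.loc[common], vb.loc[common]
    return va.to_numpy(dtype=float), vb.to_numpy(dtype=float)


def pearson_patterns(a: PatternVector, b: PatternVector,
                     counties: pd.DataFrame,
                     zero_fill: bool = True) -> CorrelationResult:
    """Sample Pearson r between two patterns with a two-sided t-test p.

    Constant vectors leave r undefined: the result carries NaN and no
    strength class.
    """
    x, y = _aligned(a, b, counties, zero_fill)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(a.name, b.name, float("nan"), float("nan"), None)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(a.name, b.name, r, float(res.pvalue), strength_of(r))


def correlation_matrix(patterns: list[PatternVector], counties: pd.DataFrame,
                       zero_fill: bool = True) -> pd.DataFrame:
    """All unordered pattern pairs as a long-format table."""
    if len(patterns) < 2:
        raise ValueError("need at least two patterns")
    rows = []
    for a, b in itertools.combinations(patterns, 2):
        res = pearson_patterns(a, b, counties, zero_fill)
        rows.append((res.pattern_a, res.pattern_b, res.r, res.p_value, res.strength))
    return pd.DataFrame(rows, columns=["pattern_a", "pattern_b", "r",
                                       "p_value", "strength"])


# -- reserve effectiveness and gaps ----------------------------------------

RESERVE_CLASSES = ("NNR", "PNR", "NNR_or_PNR")


@dataclass(frozen=True)
class GapReport:
    """Partition of a hotspot set by one reserve class."""

    reserve_class: str
    protected_counties: frozenset[str]
    gap_counties: frozenset[str]
    protected_coverage: pd.DataFrame
    gap_coverage: pd.DataFrame
    percent_protected: float
    percent_gap: float


def effectiveness_and_gaps(hotspots, counties: pd.DataFrame,
                           occ: OccurrenceTable,
                           decimals: int = 2) -> list[GapReport]:
    """Split hotspot counties into protected vs gap per reserve class.

    Non-overlapping hotspot counties are the conservation gaps; species
    coverage tables are computed for both partitions of each class.
    """
    from .prioritize import coverage_summary  # local import avoids a cycle

    hs = sorted(hotspots.selected if hasattr(hotspots, "selected") else hotspots)
    flags = {
        "NNR": counties["nnr"],
        "PNR": counties["pnr"],
        "NNR_or_PNR": counties["nnr"] | counties["pnr"],
    }
    reports = []
    for cls in RESERVE_CLASSES:
        f = flags[cls]
        protected = frozenset(c for c in hs if bool(f.loc[c]))
        gap = frozenset(hs) - protected
        n = len(hs)
        reports.append(GapReport(
            reserve_class=cls,
            protected_counties=protected,
            gap_counties=gap,
            protected_coverage=coverage_summary(protected, occ, decimals),
            gap_coverage=coverage_summary(gap, occ, decimals),
            percent_protected=percent(len(protected), n, decimals) if n else 0.0,
            percent_gap=percent(len(gap), n, decimals) if n else 0.0,
        ))
    return reports


# -- priority-group composition --------------------------------------------


@dataclass(frozen=True)
class PriorityComposition:
    """Disjoint priority partition of the taxa recorded in a county set:
    threatened first, then endemic (excluding threatened), then the rest."""

    threatened: frozenset[str]
    endemic_excl_threatened: frozenset[str]
    remaining: frozenset[str]
    counts: dict[str, int]
    percents: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition_breakdown(county_set, occ: OccurrenceTable,
                          decimals: int = 2) -> PriorityComposition:
    """Partition the taxa recorded in ``county_set`` by conservation
    priority; percents are of each group's study-wide recorded total."""
    if hasattr(county_set, "selected"):
        county_set = county_set.selected
    taxa = occ.taxa
    thr_mask = taxa["threat_status"].isin(["VU", "EN", "CR"])
    end_mask = taxa["endemic"] & ~thr_mask
    rem_mask = ~thr_mask & ~end_mask
    recorded = set(occ.recorded_taxa)
    inside = set(occ.taxa_in(county_set))
    groups = {
        "threatened": frozenset(taxa.index[thr_mask]) & frozenset(inside),
        "endemic_excl_threatened": frozenset(taxa.index[end_mask]) & frozenset(inside),
        "remaining": frozenset(taxa.index[rem_mask]) & frozenset(inside),
    }
    totals = {
        "threatened": len(set(taxa.index[thr_mask]) & recorded),
        "endemic_excl_threatened": len(set(taxa.index[end_mask]) & recorded),
        "remaining": len(set(taxa.index[rem_mask]) & recorded),
    }
    counts = {k: len(v) for k, v in groups.items()}
    percents = {k: (percent(counts[k], totals[k], decimals) if totals[k] else 0.0)
                for k in groups}
    return PriorityComposition(groups["threatened"],
                               groups["endemic_excl_threatened"],
                               groups["remaining"], counts, percents)


def composition_long_table(named_sets: dict[str, "object"],
                           occ: OccurrenceTable,
                           decimals: int = 2) -> pd.DataFrame:
    """Chord-diagram-ready long table: (set, priority group, species count,
    percent of the group's study-wide recorded total)."""
    rows = []
    for set_name, cset in named_sets.items():
        comp = composition_breakdown(cset, occ, decimals)
        for g in ("threatened", "endemic_excl_threatened", "remaining"):
            rows.append((set_name, g, comp.counts[g], comp.percents[g]))
    return pd.DataFrame(rows, columns=["county_set", "priority_group",
                                       "species_count", "percent_of_group"])
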