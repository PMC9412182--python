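"""Iterative complementarity (greedy set cover) over counties.

At each step every unselected county is scored by its gain — the number
of not-yet-covered subset taxa it contains — and all counties tied for
the maximal positive gain are selected simultaneously (deterministic;
avoids dropping counties that hold equally many novel taxa). Iteration
stops when every recorded subset taxon is covered; zero-gain counties
are never selected, so the loop terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OccurrenceTable, PatternVector
from .metrics import SUBSET_ALL, TaxonSubsetSpec


@dataclass(frozen=True)
class ComplementarityStep:
    step_index: int                      # 1-based
    gains: dict[str, int]                # county_id -> taxa newly covered

    @property
    def counties(self) -> list[str]:
        return sorted(self.gains)


@dataclass(frozen=True)
class ComplementaritySelection:
    """Full trace of a greedy complementary run."""

    steps: tuple[ComplementarityStep, ...]
    covered: frozenset[str]              # all recorded subset taxa

    @property
    def selected_counties(self) -> list[str]:
        out: list[str] = []
        for s in self.steps:
            out.extend(s.counties)
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = [(s.step_index, c, s.gains[c])
                for s in self.steps for c in s.counties]
        return pd.DataFrame(rows, columns=["step", "county_id", "gain"])


def greedy_complementary_cover(occ: OccurrenceTable,
                               subset: TaxonSubsetSpec = SUBSET_ALL,
                               ties: str = "all") -> ComplementaritySelection:
    """Run the iterative complementary algorithm until full coverage.

    ties="all" selects every county tied for the maximal gain in one
    step (gains recorded against the pre-step covered set); ties="first"
    selects only the lexicographically first tied county per step.
    """
    if ties not in ("all", "first"):
        raise ValueError("ties must be 'all' or 'first'")
    cols = subset.select(occ)
    m = occ.matrix[cols].to_numpy()          # counties x subset taxa
    recorded = m.any(axis=0)
    if not recorded.any():
        raise ValueError(f"no recorded taxa in subset {subset.name!r}")
    county_ids = np.array(occ.county_ids)
    taxon_ids = np.array(list(cols))

    uncovered = recorded.copy()
    unselected = np.ones(len(county_ids), dtype=bool)
    steps: list[ComplementarityStep] = []
    step_no = 0
    while uncovered.any():
        gains = m[:, uncovered].sum(axis=1)
        gains[~unselected] = 0
        best = gains.max()
        assert best > 0, "uncovered taxa must occur in some unselected county"
        tied = np.flatnonzero((gains == best) & unselected)
        if ties == "first":
            tied = tied[:1]
        step_no += 1
        steps.append(ComplementarityStep(
            step_no, {county_ids[i]: int(best) for i in tied}))
        newly = m[tied].any(axis=0)
        uncovered &= ~newly
        unselected[tied] = False
    covered = frozenset(taxon_ids[recorded])
    return ComplementaritySelection(tuple(steps), covered)


def complementarity_pattern(selection: ComplementaritySelection,
                            occ_or_counties, name: str = "comp") -> PatternVector:
    """Per-county pattern: the gain at selection time, 0 if never selected."""
    counties = getattr(occ_or_counties, "counties", occ_or_counties)
    idx = counties.index if hasattr(counties, "index") else pd.Index(counties)
    vals = pd.Series(0.0, index=idx)
    for s in selection.steps:
        for c, g in s.gains.items():
            vals[c] = float(g)
    return PatternVector(name, vals)
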