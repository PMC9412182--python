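"""Per-county diversity metrics.

Implements the per-county distribution patterns the hotspot pipeline
ranks: species richness over taxon subsets, Faith's phylogenetic
diversity (PD), phylogenetic endemism (PE, Rosauer-style: each branch
length divided by the number of counties holding any of its descendant
tips), weighted endemism (WE, inverse-range-size richness), max
standardization, and the combined spatial-phylogenetics score
(standardized PD + PE + WE).

Off-tree taxa (on_tree = False) contribute to richness and WE but are
skipped by PD/PE; the count of such taxa is logged once per pattern
computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import OccurrenceTable, PatternVector, Phylogeny

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonSubsetSpec:
    """A named predicate selecting rows of the taxon table.

    ``mask`` maps the taxa DataFrame to a boolean Series (a vectorized
    pure function of the per-taxon record).
    """

    name: str
    mask: Callable[[pd.DataFrame], pd.Series]

    def select(self, occ: OccurrenceTable) -> pd.Index:
        m = self.mask(occ.taxa)
        return occ.taxa.index[m.to_numpy(dtype=bool)]


def _threatened(t: pd.DataFrame) -> pd.Series:
    return t["threat_status"].isin(["VU", "EN", "CR"])


SUBSET_ALL = TaxonSubsetSpec("seed", lambda t: pd.Series(True, index=t.index))
SUBSET_ANGIOSPERM = TaxonSubsetSpec("angiosperm", lambda t: t["group"] == "angiosperm")
SUBSET_GYMNOSPERM = TaxonSubsetSpec("gymnosperm", lambda t: t["group"] == "gymnosperm")
SUBSET_ENDEMIC = TaxonSubsetSpec("endemic", lambda t: t["endemic"])
SUBSET_THREATENED = TaxonSubsetSpec("threatened", _threatened)

STANDARD_SUBSETS = {
    s.name: s for s in (SUBSET_ALL, SUBSET_ANGIOSPERM, SUBSET_GYMNOSPERM,
                        SUBSET_ENDEMIC, SUBSET_THREATENED)
}


def species_richness(occ: OccurrenceTable, subset: TaxonSubsetSpec = SUBSET_ALL,
                     name: str | None = None) -> PatternVector:
    """Number of subset taxa recorded in each county."""
    cols = subset.select(occ)
    if len(cols) == 0:
        logger.warning("subset %r selects no taxa; richness is all-zero", subset.name)
    vals = occ.matrix[cols].sum(axis=1).astype(float)
    return PatternVector(name or f"{subset.name}_richness", vals)


def weighted_endemism(occ: OccurrenceTable, subset: TaxonSubsetSpec = SUBSET_ALL,
                      name: str = "WE") -> PatternVector:
    """Per-county sum of 1 / range-size over resident subset taxa.

    Range size is the number of occupied counties; taxa with no records
    contribute nothing anywhere, so the column sums to the number of
    recorded subset taxa.
    """
    cols = subset.select(occ)
    m = occ.matrix[cols].to_numpy()
    ranges = m.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(ranges > 0, 1.0 / ranges, 0.0)
    vals = pd.Series(m @ inv, index=occ.counties.index)
    return PatternVector(name, vals)


# -- phylogenetic metrics --------------------------------------------------


def _edge_arrays(phylo: Phylogeny) -> tuple[np.ndarray, list, list[str]]:
    """Postorder edge list: lengths, per-edge descendant tip index sets."""
    tips: list[str] = []
    edges = []
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            node._tipidx = len(tips)
            tips.append(node.taxon.label)
        edges.append(node)
    lengths = np.array([n.edge.length or 0.0 for n in edges])
    return lengths, edges, tips


def faith_pd(phylo: Phylogeny, tip_set: set[str],
             include_root: bool = True) -> float:
    """Faith's PD of a tip set: summed branch length of the path union.

    With ``include_root`` the union of root-to-tip paths is used (the
    Biodiverse default); without it, only the minimal spanning subtree
    below the most recent common ancestor counts. The empty set has PD 0.
    """
    tips = set(phylo.tip_labels)
    unknown = set(tip_set) - tips
    if unknown:
        raise ValueError(f"tip ids not on tree: {sorted(unknown)}")
    if not tip_set:
        return 0.0
    total = len(tip_set)
    pd_sum = 0.0
    counts: dict = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in tip_set else 0
        else:
            c = sum(counts[ch] for ch in node.child_nodes())
        counts[node] = c
        if node is phylo.tree.seed_node:
            continue
        length = node.edge.length or 0.0
        if include_root:
            if c > 0:
                pd_sum += length
        else:
            if 0 < c < total:
                pd_sum += length
    return pd_sum


def _branch_county_incidence(phylo: Phylogeny, occ: OccurrenceTable
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch county incidence.

    Returns (lengths, A) where A[e, c] is True when branch e has at least
    one descendant tip recorded in county c. Branches hanging off the
    root are included; the root itself carries no branch.
    """
    tip_labels = set(phylo.tip_labels)
    on_tree = occ.taxa.index[occ.taxa["on_tree"]]
    usable = [t for t in on_tree if t in tip_labels]
    off = len(set(occ.recorded_taxa) - set(usable))
    if off:
        logger.info("%d recorded taxa are off-tree and skipped by PD/PE", off)
    m = occ.matrix
    n_counties = len(occ.counties)
    col = {t: m[t].to_numpy() for t in usable}
    zeros = np.zeros(n_counties, dtype=bool)

    lengths = []
    rows = []
    cache: dict = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            vec = col.get(node.taxon.label, zeros)
        else:
            vec = zeros
            for ch in node.child_nodes():
                vec = vec | cache.pop(ch)
        cache[node] = vec
        if node is phylo.tree.seed_node:
            continue
        lengths.append(node.edge.length or 0.0)
        rows.append(vec)
    return np.asarray(lengths), np.array(rows)


def pd_pattern(phylo: Phylogeny, occ: OccurrenceTable,
               include_root: bool = True, name: str = "PD") -> PatternVector:
    """Faith PD of each county's on-tree taxon set."""
    if include_root:
        lengths, A = _branch_county_incidence(phylo, occ)
        vals = pd.Series(lengths @ A, index=occ.counties.index)
    else:
        tips = set(phylo.tip_labels)
        on_tree = [t for t in occ.taxa.index[occ.taxa["on_tree"]] if t in tips]
        m = occ.matrix[on_tree]
        vals = pd.Series(
            [faith_pd(phylo, set(m.columns[m.loc[c]]), include_root=False)
             for c in occ.counties.index],
            index=occ.counties.index, dtype=float)
    return PatternVector(name, vals)


def phylogenetic_endemism(phylo: Phylogeny, occ: OccurrenceTable,
                          name: str = "PE") -> PatternVector:
    """Range-weighted PD: each branch contributes length / R_b to every
    county in its range, where R_b is the number of counties holding any
    descendant tip of the branch. Summed over counties, PE returns the PD
    of the full recorded on-tree assemblage."""
    lengths, A = _branch_county_incidence(phylo, occ)
    ranges = A.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ranges > 0, lengths / ranges, 0.0)
    vals = pd.Series(w @ A, index=occ.counties.index)
    return PatternVector(name, vals)


# -- standardization and combination ---------------------------------------


def standardize(pattern: PatternVector) -> PatternVector:
    """Divide by the maximum value; an all-zero pattern stays zero (warned)."""
    mx = float(pattern.values.max()) if len(pattern.values) else 0.0
    if mx <= 0:
        logger.warning("pattern %r is all-zero; standardized to zeros", pattern.name)
        std = pattern.values * 0.0
    else:
        std = pattern.values / mx
    return PatternVector(pattern.name, pattern.values, std)


def phylo_combined_score(pd_pat: PatternVector, pe_pat: PatternVector,
                         we_pat: PatternVector,
                         name: str = "phylo_combined") -> PatternVector:
    """Sum of the three standardized spatial-phylogenetic patterns, in [0, 3]."""
    pats = (pd_pat, pe_pat, we_pat)
    for p in pats:
        if not p.is_standardized:
            raise ValueError(f"pattern {p.name!r} is not standardized")
    idx = pats[0].standardized.index
    for p in pats[1:]:
        if not p.standardized.index.equals(idx):
            raise ValueError("patterns are defined on different county sets")
    vals = sum(p.standardized for p in pats)
    return PatternVector(name, vals)
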