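"""Independent brute-force oracles used to check the implementation.

Each function recomputes a quantity by the most literal possible method
(explicit path enumeration, double loops, exhaustive search) without
sharing code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def root_path_edges(phylo, tip_label):
    """Set of edge ids on the root-to-tip path."""
    node = next(n for n in phylo.tree.leaf_node_iter()
                if n.taxon.label == tip_label)
    edges = set()
    while node is not phylo.tree.seed_node:
        edges.add(id(node.edge))
        node = node.parent_node
    return edges


def pd_bruteforce(phylo, tip_set):
    """Faith PD (root path included) by explicit edge-set union."""
    if not tip_set:
        return 0.0
    union = set()
    for t in tip_set:
        union |= root_path_edges(phylo, t)
    lengths = {id(n.edge): (n.edge.length or 0.0)
               for n in phylo.tree.preorder_node_iter()
               if n is not phylo.tree.seed_node}
    return sum(lengths[e] for e in union)


def pe_bruteforce(phylo, occ):
    """PE by a double loop over branches x counties."""
    m = occ.matrix
    tips = set(phylo.tip_labels)
    county_taxa = {
        c: {t for t in m.columns[m.loc[c]]
            if t in tips and occ.taxa.loc[t, "on_tree"]}
        for c in occ.counties.index
    }
    branches = []
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            continue
        desc = {leaf.taxon.label for leaf in node.leaf_iter()}
        branches.append((node.edge.length or 0.0, desc))
    pe = {}
    for c, taxa in county_taxa.items():
        total = 0.0
        for length, desc in branches:
            holders = [cc for cc, tt in county_taxa.items() if tt & desc]
            if taxa & desc:
                total += length / len(holders)
        pe[c] = total
    return pe


def we_bruteforce(occ, taxon_ids=None):
    """WE by direct per-taxon summation."""
    m = occ.matrix
    taxon_ids = list(taxon_ids) if taxon_ids is not None else list(m.columns)
    out = {}
    for c in occ.counties.index:
        total = 0.0
        for t in taxon_ids:
            if m.loc[c, t]:
                total += 1.0 / int(m[t].sum())
        out[c] = total
    return out


def richness_recount(occ, taxon_ids=None):
    """Per-county set-size recount by an independent loop."""
    taxon_ids = set(taxon_ids) if taxon_ids is not None else set(occ.taxa.index)
    counts = {c: 0 for c in occ.counties.index}
    seen = set()
    for _, row in occ.presence.iterrows():
        key = (row["taxon_id"], row["county_id"])
        if key in seen or row["taxon_id"] not in taxon_ids:
            continue
        seen.add(key)
        counts[row["county_id"]] += 1
    return counts


def optimal_cover_size(sets_by_county, universe):
    """Minimal number of counties covering the universe, by exhaustion."""
    ids = list(sets_by_county)
    for k in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            cov = set()
            for c in combo:
                cov |= sets_by_county[c]
            if universe <= cov:
                return k
    raise AssertionError("universe not coverable")


def pearson_closed_form(x, y):
    """Textbook two-pass Pearson coefficient."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)
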