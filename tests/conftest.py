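import numpy as np
import pandas as pd
import pytest

import phylohotspots as ph


def make_counties(ids, areas=None, provinces=None, nnr=None, pnr=None):
    n = len(ids)
    return pd.DataFrame({
        "county_id": list(ids),
        "province_id": provinces or ["P01"] * n,
        "area_km2": areas if areas is not None else [100.0] * n,
        "nnr": nnr if nnr is not None else [False] * n,
        "pnr": pnr if pnr is not None else [False] * n,
    }).set_index("county_id")


def make_taxa(ids, group="angiosperm", endemic=False, threat="none",
              on_tree=True):
    def expand(v):
        return list(v) if isinstance(v, (list, tuple)) else [v] * len(ids)
    return pd.DataFrame({
        "taxon_id": list(ids),
        "group": expand(group),
        "endemic": expand(endemic),
        "threat_status": expand(threat),
        "on_tree": expand(on_tree),
    }).set_index("taxon_id")


def make_occ(pairs, taxa=None, counties=None, **kw):
    t_ids = sorted({t for t, _ in pairs})
    c_ids = sorted({c for _, c in pairs})
    taxa = taxa if taxa is not None else make_taxa(t_ids, **kw)
    counties = counties if counties is not None else make_counties(c_ids)
    presence = pd.DataFrame(pairs, columns=["taxon_id", "county_id"])
    return ph.OccurrenceTable(taxa, counties, presence)


def random_instance(rng, max_tips=50, max_counties=40):
    """Random tree + occurrence table for identity checks."""
    n_tips = int(rng.integers(2, max_tips + 1))
    n_counties = int(rng.integers(2, max_counties + 1))
    extra = int(rng.integers(0, 6))
    phylo = ph.simulate_phylogeny(n_tips, int(rng.integers(2**31 - 1)))
    tips = sorted(phylo.tip_labels)
    taxon_ids = tips + [f"X{i:03d}" for i in range(extra)]
    county_ids = [f"C{i:03d}" for i in range(n_counties)]
    pairs = []
    for t in taxon_ids:
        k = int(rng.integers(1, n_counties + 1))
        for c in rng.choice(county_ids, size=k, replace=False):
            pairs.append((t, str(c)))
    taxa = make_taxa(taxon_ids, on_tree=[t in set(tips) for t in taxon_ids])
    occ = make_occ(pairs, taxa=taxa, counties=make_counties(county_ids))
    return phylo, occ


@pytest.fixture(scope="session")
def small_dataset():
    """Mid-size synthetic study used by several integration tests."""
    params = ph.SimulationParams(n_rows=10, n_cols=10, n_provinces=4,
                                 n_taxa=300, n_centers=4)
    return ph.simulate_dataset(params, seed=11)
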