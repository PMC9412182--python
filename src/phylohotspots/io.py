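"""Domain types and delimited-text readers/writers.

The analysis operates on three tables (taxa, counties, presence pairs), a
rooted phylogeny with branch lengths, and a small configuration object.
All on-disk formats are plain UTF-8 comma-delimited text with headers;
phylogenies are newick.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

THREAT_LEVELS = ("none", "VU", "EN", "CR")
GROUPS = ("angiosperm", "gymnosperm")

TAXA_COLUMNS = ["taxon_id", "group", "endemic", "threat_status", "on_tree"]
COUNTY_COLUMNS = ["county_id", "province_id", "area_km2", "nnr", "pnr"]
PRESENCE_COLUMNS = ["taxon_id", "county_id"]


class FormatError(ValueError):
    """A file does not follow its declared schema."""


class ReferentialError(ValueError):
    """A presence pair references an undeclared taxon or county."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the hotspot pipeline.

    area_fractions
        Cumulative land-area fractions at which hotspot sets are cut
        (defaults follow the 5/10/17% Aichi-style thresholds).
    min_algorithms
        A county enters the integrated candidate pool when at least this
        many of the three algorithms (richness, complementarity, spatial
        phylogenetics) flag it as a hotspot.
    percent_decimals
        Decimal places for half-up percent reporting.
    zero_fill
        Extend pattern vectors with zeros over all declared counties
        before correlation.
    pd_include_root
        Include the root path in Faith PD (Biodiverse default).
    """

    area_fractions: tuple[float, ...] = (0.05, 0.10, 0.17)
    min_algorithms: int = 2
    percent_decimals: int = 2
    random_seed: int = 0
    zero_fill: bool = True
    pd_include_root: bool = True

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.area_fractions)
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError("area_fractions must lie in (0, 1]")
        if list(fr) != sorted(fr):
            raise ValueError("area_fractions must be sorted ascending")
        object.__setattr__(self, "area_fractions", fr)
        if self.min_algorithms < 1:
            raise ValueError("min_algorithms must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a key: value config file (YAML subset)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must be a key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "area_fractions" in raw:
            raw["area_fractions"] = tuple(raw["area_fractions"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            "area_fractions": list(self.area_fractions),
            "min_algorithms": self.min_algorithms,
            "percent_decimals": self.percent_decimals,
            "random_seed": self.random_seed,
            "zero_fill": self.zero_fill,
            "pd_include_root": self.pd_include_root,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class OccurrenceTable:
    """Validated taxa/counties/presence triple.

    ``taxa`` is indexed by taxon_id with columns group, endemic,
    threat_status, on_tree; ``counties`` is indexed by county_id with
    columns province_id, area_km2, nnr, pnr (extra generator columns are
    tolerated and ignored by the analysis); ``presence`` holds deduplicated
    (taxon_id, county_id) pairs.
    """

    def __init__(self, taxa: pd.DataFrame, counties: pd.DataFrame,
                 presence: pd.DataFrame) -> None:
        taxa = taxa.copy()
        counties = counties.copy()
        if taxa.index.name != "taxon_id":
            taxa = taxa.set_index("taxon_id")
        if counties.index.name != "county_id":
            counties = counties.set_index("county_id")
        if taxa.index.has_duplicates:
            dup = taxa.index[taxa.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon_id: {dup}")
        if counties.index.has_duplicates:
            dup = counties.index[counties.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate county_id: {dup}")
        bad = taxa.loc[~taxa["threat_status"].isin(THREAT_LEVELS)]
        if len(bad):
            raise FormatError(
                f"invalid threat_status values: {sorted(bad['threat_status'].unique())}")
        bad = taxa.loc[~taxa["group"].isin(GROUPS)]
        if len(bad):
            raise FormatError(
                f"invalid group values: {sorted(bad['group'].unique())}")
        if (counties["area_km2"] <= 0).any():
            off = counties.index[counties["area_km2"] <= 0].tolist()
            raise FormatError(f"non-positive area for counties: {off}")

        n_raw = len(presence)
        presence = (presence[PRESENCE_COLUMNS]
                    .drop_duplicates()
                    .sort_values(PRESENCE_COLUMNS)
                    .reset_index(drop=True))
        if n_raw != len(presence):
            logger.info("presence dedup: %d rows -> %d pairs", n_raw, len(presence))

        unknown_taxa = set(presence["taxon_id"]) - set(taxa.index)
        unknown_counties = set(presence["county_id"]) - set(counties.index)
        if unknown_taxa or unknown_counties:
            raise ReferentialError(
                "presence references undeclared entries: "
                f"taxa {sorted(unknown_taxa)}, counties {sorted(unknown_counties)}")

        self.taxa = taxa
        self.counties = counties
        self.presence = presence

    # -- derived structure -------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.taxa.index)

    @property
    def county_ids(self) -> list[str]:
        return list(self.counties.index)

    @cached_property
    def matrix(self) -> pd.DataFrame:
        """Boolean presence/absence matrix, counties x taxa."""
        arr = np.zeros((len(self.counties), len(self.taxa)), dtype=bool)
        arr[
            self.counties.index.get_indexer(self.presence["county_id"]),
            self.taxa.index.get_indexer(self.presence["taxon_id"]),
        ] = True
        return pd.DataFrame(arr, index=self.counties.index, columns=self.taxa.index)

    @cached_property
    def range_sizes(self) -> pd.Series:
        """Occupied-county count per taxon (0 for unrecorded taxa)."""
        return self.matrix.sum(axis=0).astype(int)

    @cached_property
    def recorded_taxa(self) -> pd.Index:
        return self.range_sizes.index[self.range_sizes > 0]

    def taxa_in(self, county_ids: Iterable[str]) -> pd.Index:
        """Taxa with at least one record inside the given county set."""
        ids = list(county_ids)
        if not ids:
            return self.taxa.index[:0]
        sub = self.matrix.loc[ids]
        return sub.columns[sub.any(axis=0)]

    def with_taxa(self, taxa: pd.DataFrame) -> "OccurrenceTable":
        return OccurrenceTable(taxa, self.counties, self.presence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccurrenceTable):
            return NotImplemented
        return (self.taxa[["group", "endemic", "threat_status", "on_tree"]]
                .equals(other.taxa[["group", "endemic", "threat_status", "on_tree"]])
                and self.counties[COUNTY_COLUMNS[1:]].equals(
                    other.counties[COUNTY_COLUMNS[1:]])
                and self.presence.equals(other.presence))


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths whose tips name taxa."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        tips = self.tip_labels
        if len(tips) == 0:
            raise FormatError("phylogeny has no tips")
        if len(tips) != len(set(tips)):
            raise FormatError("duplicate tip labels in phylogeny")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.preorder_edge_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def prune_to(self, labels: set[str]) -> "Phylogeny":
        keep = [t for t in self.tree.taxon_namespace if t.label in labels]
        tree = self.tree.clone(depth=1)
        tree.retain_taxa(keep)
        return Phylogeny(tree)


@dataclass(frozen=True)
class PatternVector:
    """A named per-county non-negative distribution pattern.

    ``values`` maps county_id -> raw value; ``standardized`` (set by
    :func:`phylohotspots.metrics.standardize`) is values / max(values).
    """

    name: str
    values: pd.Series
    standardized: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        if (v < 0).any():
            raise ValueError(f"pattern {self.name!r} has negative values")
        object.__setattr__(self, "values", v)

    @property
    def is_standardized(self) -> bool:
        return self.standardized is not None

    def reindexed(self, county_ids: Iterable[str], fill: float = 0.0) -> "PatternVector":
        idx = pd.Index(county_ids)
        std = self.standardized.reindex(idx, fill_value=fill) if self.is_standardized else None
        return PatternVector(self.name, self.values.reindex(idx, fill_value=fill), std)


# -- readers / writers -----------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_bool(s: pd.Series, path: str | Path, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, True: True, False: False}
    out = s.map(lambda x: mapping.get(x if isinstance(x, bool) else str(x).strip().lower()))
    if out.isna().any():
        raise FormatError(f"{path}: column {col!r} must contain true/false")
    return out.astype(bool)


def read_occurrences(occ_path: str | Path, taxa_path: str | Path,
                     counties_path: str | Path) -> OccurrenceTable:
    """Read and validate the three input tables.

    Duplicate presence rows are collapsed to a single pair; counts before
    and after deduplication are logged.
    """
    taxa = pd.read_csv(taxa_path, dtype=str)
    _require_columns(taxa, TAXA_COLUMNS, taxa_path)
    for col in ("endemic", "on_tree"):
        taxa[col] = _parse_bool(taxa[col], taxa_path, col)
    counties = pd.read_csv(counties_path, dtype=str)
    _require_columns(counties, COUNTY_COLUMNS, counties_path)
    counties["area_km2"] = counties["area_km2"].astype(float)
    for col in ("nnr", "pnr"):
        counties[col] = _parse_bool(counties[col], counties_path, col)
    presence = pd.read_csv(occ_path, dtype=str)
    _require_columns(presence, PRESENCE_COLUMNS, occ_path)
    return OccurrenceTable(taxa, counties, presence)


def write_occurrences(occ: OccurrenceTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables back to delimited text; inverse of read_occurrences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": out / "taxa.csv",
        "counties": out / "counties.csv",
        "occurrences": out / "occurrences.csv",
    }
    taxa = occ.taxa.reset_index()[TAXA_COLUMNS]
    counties = occ.counties.reset_index()[COUNTY_COLUMNS]
    for df in (taxa, counties):
        for col in df.columns:
            if df[col].dtype == bool:
                df[col] = df[col].map({True: "true", False: "false"})
    taxa.to_csv(paths["taxa"], index=False)
    counties.to_csv(paths["counties"], index=False)
    occ.presence.to_csv(paths["occurrences"], index=False)
    return paths


def read_phylogeny(path: str | Path, occ: OccurrenceTable) -> Phylogeny:
    """Parse a newick phylogeny and reconcile its tips with the taxon table.

    Tips absent from ``occ.taxa`` are pruned (and logged); taxa absent from
    the tree get on_tree = False in ``occ.taxa`` (updated in place).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    if tree.is_rooted is False and tree.seed_node is not None \
            and len(tree.seed_node.child_nodes()) > 2:
        raise FormatError(f"{path}: tree is unrooted (basal polytomy, [&U])")
    tree.is_rooted = True
    phylo = Phylogeny(tree)
    declared = set(occ.taxa.index)
    tips = set(phylo.tip_labels)
    stray = tips - declared
    if stray:
        logger.warning("pruning %d tree tips absent from taxa table: %s",
                       len(stray), sorted(stray)[:10])
        phylo = phylo.prune_to(tips & declared)
        if not set(phylo.tip_labels):
            raise FormatError(f"{path}: no tree tip matches a declared taxon")
    on_tree = occ.taxa.index.isin(set(phylo.tip_labels))
    n_off = int((~on_tree).sum())
    if n_off:
        logger.info("%d taxa are not on the phylogeny (on_tree=false)", n_off)
    occ.taxa["on_tree"] = on_tree
    return phylo


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write one CSV per named table plus a JSON manifest/summary.

    Returns the manifest: {name: {"path": ..., "rows": ...}, ...}.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, dict] = {}
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            manifest[name] = {"path": str(p), "rows": int(len(df))}
        with open(out / "report_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except OSError as exc:
        raise OSError(f"cannot write report to {out}: {exc}") from exc
    return manifest
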