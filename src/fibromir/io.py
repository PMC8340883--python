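"""Readers and writers for every external file the pipeline touches.

All tabular formats are UTF-8, tab-separated, with a header row.  Feature and
gene identifiers are opaque strings; no species-prefix parsing is attempted.
Readers validate strictly and raise :class:`FormatError` naming the offending
line and field — malformed cells are never silently coerced.

Formats
-------
count TSV + design TSV    raw integer read counts and the sample -> group map
target TSV                miRWalk-style miRNA->gene edges with per-program
                          evidence flags (targetscan, mirdb, mirtarbase)
GMT                       named gene sets (name, description, genes...)
PPI TSV                   STRING-style scored undirected edges
SIF / GraphML             Cytoscape-loadable network exports
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

GROUP_CONTROL = "control"
GROUP_FIBROTIC = "fibrotic"
GROUP_RECOVERY = "recovery"

#: evidence columns of a target-map table, one per prediction program
TARGET_PROGRAMS = ("targetscan", "mirdb", "mirtarbase")


class FormatError(ValueError):
    """A file violated its expected format; message names line and field."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw integer read counts, features x samples, with a group design.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by feature identifier with one column per
        sample identifier.
    design
        Series mapping every sample identifier to its group label (typically
        ``control`` / ``fibrotic`` / ``recovery``, but arbitrary labels are
        accepted).
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise FormatError("empty count matrix")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature identifier {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric count cell")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count for feature {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count for feature {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} missing from design")
        # keep only samples present in the matrix, in matrix order
        self.design = self.design.loc[self.counts.columns].astype(str)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])


def read_count_matrix(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Load a count TSV (first column = feature id, header = sample ids)
    together with its sample->group design TSV.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError(f"{path.name}: no sample columns")
    cells = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, val in enumerate(raw[col]):
            line = i + 2  # header is line 1
            try:
                f = float(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name} line {line}, column {col!r}: "
                    f"non-numeric count {val!r}"
                ) from None
            if f < 0:
                raise FormatError(
                    f"{path.name} line {line}, column {col!r}: negative count {val!r}"
                )
            if f != int(f):
                raise FormatError(
                    f"{path.name} line {line}, column {col!r}: "
                    f"non-integer count {val!r}"
                )
            cells[i, j] = int(f)
    counts = pd.DataFrame(cells, index=raw.index, columns=raw.columns)
    design = read_design(design_path)
    return CountMatrix(counts, design)


def read_design(path: str | Path) -> pd.Series:
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in tab.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    if tab["sample"].duplicated().any():
        dup = tab["sample"][tab["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path.name}: duplicate sample {dup!r}")
    return pd.Series(tab["group"].values, index=tab["sample"].values, name="group")


def write_count_matrix(cm: CountMatrix, path: str | Path, design_path: str | Path) -> None:
    cm.counts.rename_axis("feature").to_csv(path, sep="\t")
    pd.DataFrame({"sample": cm.design.index, "group": cm.design.values}).to_csv(
        design_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# miRNA -> gene target maps
# ---------------------------------------------------------------------------


@dataclass
class TargetMap:
    """Predicted miRNA->gene edges with per-program evidence flags."""

    table: pd.DataFrame  # columns: mirna, gene, targetscan, mirdb, mirtarbase

    def __post_init__(self) -> None:
        need = ["mirna", "gene", *TARGET_PROGRAMS]
        for col in need:
            if col not in self.table.columns:
                raise FormatError(f"target map missing column {col!r}")
        self.table = self.table[need].reset_index(drop=True)
        dup = self.table.duplicated(subset=["mirna", "gene"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise FormatError(f"duplicate target edge ({row['mirna']}, {row['gene']})")
        for col in TARGET_PROGRAMS:
            vals = self.table[col]
            if not vals.isin([0, 1]).all():
                bad = vals[~vals.isin([0, 1])].iloc[0]
                raise FormatError(f"evidence flag {col!r} must be 0/1, got {bad!r}")

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(zip(self.table["mirna"], self.table["gene"]))

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self.table["mirna"])

    def targets_of(self, mirna: str) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["mirna"] == mirna, "gene"])

    def support(self) -> pd.Series:
        """Number of prediction programs supporting each edge."""
        return self.table[list(TARGET_PROGRAMS)].sum(axis=1)


def read_target_map(path: str | Path, min_programs: int = 1) -> TargetMap:
    """Load a target TSV, keeping edges supported by >= ``min_programs`` of the
    three prediction programs."""
    if min_programs not in (1, 2, 3):
        raise ValueError(f"min_programs must be 1, 2 or 3, got {min_programs}")
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    for col in ("mirna", "gene", *TARGET_PROGRAMS):
        if col not in tab.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    for col in TARGET_PROGRAMS:
        bad = ~tab[col].isin([0, 1])
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path.name} line {line}, column {col!r}: flag must be 0/1"
            )
    tm = TargetMap(tab)
    keep = tm.support() >= min_programs
    return TargetMap(tm.table[keep].reset_index(drop=True))


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    tm.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe; every set is a subset of the universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for s in self.sets.values():
                u |= s
            self.universe = frozenset(u)
        for name, s in self.sets.items():
            if not s <= self.universe:
                extra = sorted(s - self.universe)[0]
                raise FormatError(
                    f"gene set {name!r} contains {extra!r} outside the universe"
                )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Load a GMT file (name, description, genes..., tab-separated).

    The universe defaults to the union of all sets; if an explicit ``universe``
    is supplied, sets are restricted to it.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name} line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path.name} line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path.name} line {lineno}: set {name!r} is empty")
            sets[name] = genes
    if universe is not None:
        uni = frozenset(universe)
        sets = {name: s & uni for name, s in sets.items()}
        return GeneSetCollection(sets, uni)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# protein-protein interaction edge lists
# ---------------------------------------------------------------------------


@dataclass
class PPIEdgeList:
    """Scored undirected PPI edges (STRING combined score, 0-1000 scale)."""

    table: pd.DataFrame  # columns: gene_a, gene_b, combined_score

    def __post_init__(self) -> None:
        for col in ("gene_a", "gene_b", "combined_score"):
            if col not in self.table.columns:
                raise FormatError(f"PPI table missing column {col!r}")
        tab = self.table[["gene_a", "gene_b", "combined_score"]].copy()
        scores = tab["combined_score"].to_numpy(dtype=float)
        if np.any((scores < 0) | (scores > 1000)):
            bad = scores[(scores < 0) | (scores > 1000)][0]
            raise FormatError(f"combined score {bad} outside [0, 1000]")
        tab = tab[tab["gene_a"] != tab["gene_b"]]  # drop self-loops
        # canonical undirected orientation, keep the maximal score of duplicates
        lo = tab[["gene_a", "gene_b"]].min(axis=1)
        hi = tab[["gene_a", "gene_b"]].max(axis=1)
        tab = pd.DataFrame(
            {"gene_a": lo, "gene_b": hi, "combined_score": tab["combined_score"].values}
        )
        tab = (
            tab.groupby(["gene_a", "gene_b"], as_index=False)["combined_score"]
            .max()
            .reset_index(drop=True)
        )
        self.table = tab

    def to_graph(self, score_min: float = 0.0) -> nx.Graph:
        g = nx.Graph()
        keep = self.table[self.table["combined_score"] >= score_min]
        for a, b, s in keep.itertuples(index=False):
            g.add_edge(a, b, combined_score=float(s))
        return g


def read_ppi(path: str | Path, score_min: float = 400.0) -> PPIEdgeList:
    """Load a STRING-style edge TSV, keeping edges with combined score >=
    ``score_min`` (default 400, STRING's conventional medium confidence)."""
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    ppi = PPIEdgeList(tab)
    keep = ppi.table["combined_score"] >= score_min
    return PPIEdgeList(ppi.table[keep].reset_index(drop=True))


def write_ppi(ppi: PPIEdgeList, path: str | Path) -> None:
    ppi.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pair tables and network exports
# ---------------------------------------------------------------------------


def write_pairs_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write a miRNA-mRNA pair table (mirna, gene, pcc, p_value, ...) as TSV."""
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})


def export_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a network for Cytoscape, either as SIF (``miRNA regulates gene``
    lines) or GraphML (node/edge attributes preserved)."""
    fmt = format.lower()
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in network.edges():
                # orient miRNA -> gene when node types are annotated
                if network.nodes[v].get("node_type") == "miRNA" and (
                    network.nodes[u].get("node_type") != "miRNA"
                ):
                    u, v = v, u
                fh.write(f"{u}\tregulates\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {format!r} (use 'sif' or 'graphml')")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# small JSON helpers (truth files, stage reports)
# ---------------------------------------------------------------------------


def write_json(obj: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
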