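"""Regulatory-network construction and hub mining.

Builds the bipartite miRNA-mRNA network from retained negative pairs, mines
hub genes as the intersection of designated ECM-related gene sets among the
reversal genes (in the mouse fibrosis-reversal study this recovers the lysyl
oxidase family), extracts the first-degree-neighbor PPI subnetwork around
those hubs, and identifies key miRNAs as the triple-Venn intersection of the
miRNAs whose negative pairs hit each of three designated target categories
(ECM components, HSC activation, LOX-family regulation).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .diffexpr import DEResult
from .integrate import CLASS_POSITIVE, ReversalSet
from .io import GeneSetCollection, PPIEdgeList

__all__ = [
    "build_bipartite",
    "hub_genes_by_intersection",
    "ppi_first_degree",
    "key_mirnas_by_triple_venn",
]


def build_bipartite(
    pairs: pd.DataFrame,
    de_mirna: DEResult,
    de_gene: DEResult,
) -> nx.Graph:
    """Bipartite miRNA-gene network from negative-class pairs.

    Node attributes: ``node_type`` ("miRNA"/"gene") and ``signed_fc`` from the
    recovery-vs-fibrotic contrast. Edge attributes: ``pcc`` and ``p_value``.
    Every supplied pair must be negative-class, and both endpoints must be in
    the DE results.
    """
    if "pair_class" in pairs.columns and (pairs["pair_class"] == CLASS_POSITIVE).any():
        raise ValueError("positive-class pairs are excluded from the network")
    if (pairs["pcc"] >= 0).any():
        raise ValueError("bipartite network expects negatively correlated pairs")
    g = nx.Graph(bipartite=True)
    for row in pairs.itertuples(index=False):
        for feature, de, kind in ((row.mirna, de_mirna, "miRNA"), (row.gene, de_gene, "gene")):
            if feature not in de.table.index:
                raise ValueError(
                    f"pair member {feature!r} absent from DE result {de.contrast!r}"
                )
            if feature not in g:
                g.add_node(
                    feature,
                    node_type=kind,
                    signed_fc=float(de.table.loc[feature, "signed_fc"]),
                )
        g.add_edge(row.mirna, row.gene, pcc=float(row.pcc), p_value=float(row.p_value))
    return g


def hub_genes_by_intersection(
    gene_reversal: ReversalSet,
    collection: GeneSetCollection,
    set_names: Sequence[str],
) -> frozenset[str]:
    """Genes present in EVERY named set and in the reversal gene set."""
    if not set_names:
        raise ValueError("need at least one set name")
    result = set(gene_reversal.features)
    for name in set_names:
        if name not in collection:
            raise KeyError(f"unknown gene set {name!r}")
        result &= collection[name]
    return frozenset(result)


def ppi_first_degree(
    ppi: PPIEdgeList,
    hubs: Iterable[str],
    restrict_to: Iterable[str] | None = None,
    score_min: float = 400.0,
    hub_spoke_only: bool = False,
) -> nx.Graph:
    """First-degree-neighbor PPI subnetwork around hub genes.

    Nodes are the hubs plus their neighbors at combined score >= ``score_min``
    (optionally restricted to ``restrict_to``, e.g. the down-regulated
    reversal genes). Edges are all qualifying edges among included nodes, or
    only hub-incident ones when ``hub_spoke_only``. Each node carries
    ``degree`` (within the subnetwork) and ``is_seed`` attributes; hubs absent
    from the PPI remain as isolated seeds.
    """
    hubs = set(hubs)
    if not hubs:
        raise ValueError("hub set is empty")
    full = ppi.to_graph(score_min=score_min)
    allowed = None if restrict_to is None else set(restrict_to) | hubs
    nodes = set(hubs)
    for h in hubs & set(full.nodes):
        for nb in full.neighbors(h):
            if allowed is None or nb in allowed:
                nodes.add(nb)
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    for u, v, data in full.edges(data=True):
        if u in nodes and v in nodes:
            if hub_spoke_only and not (u in hubs or v in hubs):
                continue
            sub.add_edge(u, v, **data)
    for node in sub.nodes:
        sub.nodes[node]["degree"] = sub.degree(node)
        sub.nodes[node]["is_seed"] = node in hubs
    return sub


def key_mirnas_by_triple_venn(
    pairs: pd.DataFrame,
    collection: GeneSetCollection,
    category_names: Sequence[str],
) -> frozenset[str]:
    """miRNAs whose retained negative pairs target >= 1 gene in EACH of three
    designated categories (triple-Venn intersection)."""
    if len(set(category_names)) != 3:
        raise ValueError("exactly three distinct category names are required")
    for name in category_names:
        if name not in collection:
            raise KeyError(f"unknown gene set {name!r}")
    neg = pairs[pairs["pcc"] < 0]
    per_category = []
    for name in category_names:
        genes = collection[name]
        per_category.append(frozenset(neg.loc[neg["gene"].isin(genes), "mirna"]))
    return per_category[0] & per_category[1] & per_category[2]
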