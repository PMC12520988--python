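"""Post-processing of enriched gene sets.

Redundancy reduction by greedy Jaccard-based simplification, an undirected
weighted similarity network over the surviving sets (edge weight = Jaccard
index of their gene lists), Louvain community detection, and boolean
annotation of result tables against external gene lists (e.g. a surfaceome
inventory).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .gsea import GseaResult


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B| of two gene lists; empty inputs are an error."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("Jaccard index needs two non-empty sets")
    return len(a & b) / len(a | b)


def _gene_lists(results: GseaResult, gene_field: str) -> dict[str, list[str]]:
    if gene_field == "leading_edge":
        return results.leading_edges
    if gene_field == "members":
        return results.members
    raise ValueError(f"unknown gene_field {gene_field!r}")


def simplify_sets(results: GseaResult, similarity_cutoff: float = 0.7,
                  gene_field: str = "members") -> GseaResult:
    """Drop redundant sets: among any pair with Jaccard >= cutoff keep the
    one with the smaller adjusted p (ties: larger |NES|, then alphabetical
    id), applied greedily in ascending adjusted-p order."""
    genes = _gene_lists(results, gene_field)
    tab = results.table
    ordered_ids = sorted(tab.index.tolist(),
                         key=lambda s: (tab.at[s, "padj"], -abs(tab.at[s, "NES"]), s))
    kept: list[str] = []
    for sid in ordered_ids:
        if all(jaccard(genes[sid], genes[k]) < similarity_cutoff for k in kept):
            kept.append(sid)
    kept_index = [s for s in results.table.index if s in set(kept)]
    return GseaResult(results.table.loc[kept_index].copy(),
                      {s: results.leading_edges[s] for s in kept_index},
                      {s: results.members[s] for s in kept_index})


def build_similarity_network(results: GseaResult, gene_field: str = "leading_edge",
                             min_edge: float = 0.0) -> nx.Graph:
    """Undirected weighted network of enriched sets.

    Nodes carry NES and adjusted p; edges connect pairs whose gene-list
    Jaccard index exceeds ``min_edge``.
    """
    genes = _gene_lists(results, gene_field)
    if len(results.table) == 0:
        raise ValueError("no enriched sets to build a network from")
    g = nx.Graph()
    for sid, row in results.table.iterrows():
        g.add_node(sid, NES=float(row["NES"]), padj=float(row["padj"]))
    ids = list(results.table.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            w = jaccard(genes[a], genes[b])
            if w > min_edge:
                g.add_edge(a, b, weight=w)
    return g


def detect_communities(net: nx.Graph, resolution: float = 1.0, seed: int = 0
                       ) -> dict[str, int]:
    """Louvain modularity communities (seeded, deterministic) as node -> label."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    comms = nx.community.louvain_communities(net, weight="weight",
                                             resolution=resolution, seed=seed)
    # stable labels: communities ordered by their lexically smallest member
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: label for label, members in enumerate(comms) for node in members}


def modularity(net: nx.Graph, labels: dict[str, int]) -> float:
    groups: dict[int, set] = {}
    for node, lab in labels.items():
        groups.setdefault(lab, set()).add(node)
    return nx.community.modularity(net, list(groups.values()), weight="weight")


def annotate_membership(table: pd.DataFrame, annotation_list, label: str) -> pd.DataFrame:
    """Add a boolean column flagging rows whose id is in the annotation list."""
    ids = set(str(x) for x in annotation_list)
    if not ids:
        raise ValueError("annotation list is empty")
    out = table.copy()
    out[label] = np.asarray([str(i) in ids for i in out.index], dtype=bool)
    return out


def network_tables(net: nx.Graph, labels: dict[str, int] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (TSV-ready) of a set network."""
    nodes = pd.DataFrame([
        {"set_id": n, **net.nodes[n],
         **({"community": labels[n]} if labels else {})}
        for n in net.nodes
    ]).set_index("set_id")
    edges = pd.DataFrame(
        [{"source": a, "target": b, "jaccard": d["weight"]} for a, b, d in net.edges(data=True)],
        columns=["source", "target", "jaccard"])
    return nodes, edges
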