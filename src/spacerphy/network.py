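"""Spacer-sharing homology network between CRISPR arrays.

Arrays sharing identical spacers are presumed homologous. Each array is a
node; an undirected edge joins two arrays sharing at least ``min_shared``
unique spacers (default 2), weighted by the Jaccard similarity of their
unique spacer sets. Connected components of this graph are clusters of
homologous arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .arrays import CRISPRArray

__all__ = [
    "NetworkEdge",
    "jaccard_similarity",
    "build_network",
    "extract_clusters",
    "write_edge_list",
    "write_node_table",
]


@dataclass(frozen=True)
class NetworkEdge:
    array_a: str
    array_b: str
    shared_count: int
    jaccard: float


def jaccard_similarity(a: CRISPRArray, b: CRISPRArray) -> float:
    """Jaccard similarity of the unique spacer sets of two arrays:
    shared spacers / total unique spacers across both."""
    sa, sb = a.unique_spacers, b.unique_spacers
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def build_network(
    arrays: Sequence[CRISPRArray], min_shared: int = 2
) -> list[NetworkEdge]:
    """One edge per unordered array pair sharing >= min_shared spacers."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids in network input")
    edges: list[NetworkEdge] = []
    for a, b in combinations(arrays, 2):
        shared = len(a.unique_spacers & b.unique_spacers)
        if shared >= min_shared:
            edges.append(NetworkEdge(a.array_id, b.array_id, shared,
                                     jaccard_similarity(a, b)))
    return edges


def extract_clusters(
    edges: Iterable[NetworkEdge], arrays: Sequence[CRISPRArray]
) -> list[list[str]]:
    """Connected components, numbered 1..k by decreasing size.

    Isolated arrays form singleton clusters. Size ties are broken by the
    smallest member id so cluster numbering is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(a.array_id for a in arrays)
    g.add_edges_from((e.array_a, e.array_b) for e in edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def write_edge_list(edges: Iterable[NetworkEdge], path) -> None:
    """Cytoscape-importable TSV: array_a, array_b, shared_count, jaccard."""
    with open(path, "w") as fh:
        fh.write("array_a\tarray_b\tshared_count\tjaccard\n")
        for e in edges:
            fh.write(f"{e.array_a}\t{e.array_b}\t{e.shared_count}\t{e.jaccard:.6g}\n")


def write_node_table(clusters: Sequence[Sequence[str]], path) -> None:
    """Node table TSV with 1-based cluster assignment (isolates included)."""
    with open(path, "w") as fh:
        fh.write("array_id\tcluster\n")
        for i, members in enumerate(clusters, start=1):
            for m in members:
                fh.write(f"{m}\t{i}\n")
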