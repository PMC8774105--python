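"""Residue interaction graph and n-bridge cluster enumeration.

Contacts from one structure become edges of a bipartite graph between Met
nodes and aromatic nodes.  An n-bridge cluster is a Met whose aromatic degree
is at least n; n=3 is the motif of interest (three aromatic faces about the
thioether).  By default one *maximal* cluster is reported per qualifying Met
(a Met with 4 partners yields one cluster of size 4); a combinatorial mode
expanding every n-subset is available for sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .pair_detection import PairContact
from .structure_io import AromaticSite, MetSite, ResidueRef


@dataclass
class BridgeCluster:
    """One Met with >= n aromatic partners."""

    met: MetSite
    partners: list[tuple[AromaticSite, PairContact]]
    order: int  # n requested

    @property
    def composition(self) -> Counter:
        return Counter(a.ref.residue_name for a, _ in self.partners)

    @property
    def size(self) -> int:
        return len(self.partners)


def build_graph(contacts: list[PairContact]) -> nx.Graph:
    """Bipartite graph: Met nodes vs aromatic nodes, one edge per contact."""
    g = nx.Graph()
    for c in contacts:
        if c.met == c.aromatic:
            raise ValueError(f"contact references the same residue twice: {c.met}")
        g.add_node(c.met, bipartite="met", site=c.met_site)
        g.add_node(c.aromatic, bipartite="aromatic", site=c.aromatic_site)
        g.add_edge(c.met, c.aromatic, contact=c)
    return g


def find_n_bridges(graph: nx.Graph, n: int = 3,
                   combinatorial: bool = False) -> list[BridgeCluster]:
    """Enumerate n-bridge clusters of the interaction graph.

    Returns one maximal cluster per Met with aromatic degree >= n, partners
    sorted by (chain, residue number, insertion code).  With
    ``combinatorial``, every n-subset of partners becomes its own cluster.
    """
    if n < 2:
        raise ValueError("bridge order n must be >= 2")
    clusters: list[BridgeCluster] = []
    met_nodes = sorted(
        (node for node, data in graph.nodes(data=True) if data.get("bipartite") == "met"),
        key=_ref_key)
    for met_ref in met_nodes:
        neighbors = sorted(graph.neighbors(met_ref), key=_ref_key)
        if len(neighbors) < n:
            continue
        met_site = graph.nodes[met_ref]["site"]
        partners = [(graph.nodes[a]["site"], graph.edges[met_ref, a]["contact"])
                    for a in neighbors]
        if combinatorial:
            for subset in combinations(partners, n):
                clusters.append(BridgeCluster(met=met_site, partners=list(subset),
                                              order=n))
        else:
            clusters.append(BridgeCluster(met=met_site, partners=partners, order=n))
    return clusters


def _ref_key(ref: ResidueRef):
    return (ref.chain_id, ref.residue_number, ref.insertion_code)


def clusters_to_rows(structure_id: str, clusters: list[BridgeCluster]) -> list[dict]:
    """Flatten clusters for CSV export."""
    rows = []
    for cl in clusters:
        rows.append({
            "structure_id": structure_id,
            "met_chain": cl.met.ref.chain_id,
            "met_number": cl.met.ref.residue_number,
            "n": cl.order,
            "size": cl.size,
            "partners": ";".join(str(a.ref) for a, _ in cl.partners),
            "composition": "-".join(sorted(cl.composition.elements())),
            "distances": ";".join(f"{c.distance:.3f}" for _, c in cl.partners),
        })
    return rows
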