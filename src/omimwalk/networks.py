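"""Disease similarity network (ODSN) and bipartite association network (ODMAN).

The ODSN links two diseases whenever their phenotype similarity is strictly
above a threshold (default 0), weighted by the similarity score. The ODMAN
is the unweighted bipartite graph of verified miRNA-disease associations
(every edge weight exactly 1). Both are plain :mod:`networkx` graphs; the
random walk itself operates on the matrix (see :mod:`omimwalk.rwr`) so that
zero-weight structure is handled once, in normalization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import AssociationSet, SimilarityMatrix


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of the bipartite association network.

    Average degrees are stored at full precision; use :meth:`as_row` for the
    conventional 2-decimal display.
    """

    n_diseases: int
    n_mirnas: int
    n_associations: int
    avg_degree_diseases: float
    avg_degree_mirnas: float
    disease_degree_histogram: dict[int, int]
    mirna_degree_histogram: dict[int, int]
    n_components: int
    largest_component_fraction: float

    def as_row(self) -> dict[str, object]:
        """Summary row with averages rounded to 2 decimals for display."""
        return {
            "n_diseases": self.n_diseases,
            "n_mirnas": self.n_mirnas,
            "n_associations": self.n_associations,
            "avg_degree_diseases": round(self.avg_degree_diseases, 2),
            "avg_degree_mirnas": round(self.avg_degree_mirnas, 2),
            "n_components": self.n_components,
            "largest_component_fraction": round(
                self.largest_component_fraction, 4
            ),
        }


def build_odsn(
    sim: SimilarityMatrix, edge_threshold: float = 0.0
) -> nx.Graph:
    """Build the weighted disease similarity network.

    An edge (i, j), i != j, exists iff O(i, j) > ``edge_threshold``
    (strictly), with weight O(i, j). No self-loops.
    """
    g = nx.Graph()
    g.add_nodes_from(sim.disease_ids)
    ids = sim.disease_ids
    vals = sim.values
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = vals[i, j]
            if w > edge_threshold:
                g.add_edge(ids[i], ids[j], weight=float(w))
    return g


def build_odman(assoc: AssociationSet) -> nx.Graph:
    """Build the bipartite association network (all edge weights 1).

    miRNA nodes carry ``bipartite=0``, disease nodes ``bipartite=1``; node
    sets are exactly the identifiers occurring in the pairs.
    """
    g = nx.Graph()
    g.add_nodes_from(assoc.mirna_ids, bipartite=0)
    g.add_nodes_from(assoc.disease_ids, bipartite=1)
    g.add_edges_from(((m, d, {"weight": 1}) for m, d in assoc.pairs))
    return g


def network_stats(g: nx.Graph) -> NetworkStats:
    """Compute the descriptive statistics of a bipartite association graph.

    Components are computed treating edges as undirected. Average degrees
    satisfy the exact identity avg_degree * n_nodes == n_edges per side.
    """
    mirnas = [n for n, b in g.nodes(data="bipartite") if b == 0]
    diseases = [n for n, b in g.nodes(data="bipartite") if b == 1]
    n_assoc = g.number_of_edges()
    n_d, n_m = len(diseases), len(mirnas)
    d_hist = Counter(d for _, d in g.degree(diseases))
    m_hist = Counter(d for _, d in g.degree(mirnas))
    if g.number_of_nodes():
        comps = list(nx.connected_components(g))
        largest = max((len(c) for c in comps), default=0)
        frac = largest / g.number_of_nodes()
    else:
        comps, frac = [], 0.0
    return NetworkStats(
        n_diseases=n_d,
        n_mirnas=n_m,
        n_associations=n_assoc,
        avg_degree_diseases=n_assoc / n_d if n_d else 0.0,
        avg_degree_mirnas=n_assoc / n_m if n_m else 0.0,
        disease_degree_histogram=dict(sorted(d_hist.items())),
        mirna_degree_histogram=dict(sorted(m_hist.items())),
        n_components=len(comps),
        largest_component_fraction=frac,
    )


def write_edge_list(g: nx.Graph, path) -> None:
    """Export a graph as a (node1, node2, weight) TSV for external tools."""
    rows = sorted(
        (u, v, data.get("weight", 1)) for u, v, data in g.edges(data=True)
    )
    pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(
        path, sep="\t", index=False
    )
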