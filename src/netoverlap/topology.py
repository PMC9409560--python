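"""Topological characterisation of the subnetwork induced by a gene set.

Seven statistics describe how strongly a gene set clusters in the interactome:
edge count, size of the largest connected component ("largest subnetwork"),
mean degree, mean closeness centrality, mean shortest distance over connected
pairs, mean clustering coefficient, and mean betweenness centrality.  All
distances are unweighted hop counts on the induced subgraph.

Conventions (the induced subgraph is usually disconnected, so these matter):

* ``mean_degree`` defaults to edges per mapped node, E/N; the textbook 2E/N is
  available via ``degree_convention="2E_over_N"``.
* closeness uses the Wasserman–Faust component scaling
  ((r-1)/(n-1)) * ((r-1)/Σd) with r the node's reachable count; an isolated
  node contributes 0.
* ``mean_shortest_distance`` averages over connected unordered pairs only and
  is NaN when no such pair exists.
* betweenness is normalised by (n-1)(n-2)/2 pairs, endpoints excluded.
* nodes of degree < 2 contribute 0 to the clustering coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from collections.abc import Iterable

import networkx as nx

from netoverlap.interactome import GeneSet, induced_subgraph

__all__ = ["TopologyMetrics", "METRIC_NAMES", "topology_metrics", "subgraph_metrics"]

#: Metric names in reporting order; the first seven are the test statistics.
METRIC_NAMES = (
    "all_edges",
    "largest_subnetwork",
    "mean_degree",
    "closeness_centrality",
    "mean_shortest_distance",
    "clustering_coefficient",
    "betweenness_centrality",
)


@dataclass(frozen=True)
class TopologyMetrics:
    """The seven subnetwork statistics plus the mapped-node count."""

    all_edges: int
    largest_subnetwork: int
    mean_degree: float
    closeness_centrality: float
    mean_shortest_distance: float  # NaN if no connected pair
    clustering_coefficient: float
    betweenness_centrality: float
    n_mapped_nodes: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _mean_shortest_distance(graph: nx.Graph) -> float:
    total = 0
    n_pairs = 0
    for lengths in dict(nx.all_pairs_shortest_path_length(graph)).values():
        for d in lengths.values():
            if d > 0:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        return math.nan
    return total / n_pairs  # each unordered pair counted twice; ratio unchanged


def subgraph_metrics(
    graph: nx.Graph,
    metrics: Iterable[str] | None = None,
    degree_convention: str = "E_over_N",
) -> TopologyMetrics:
    """Compute the topology statistics of a graph directly.

    ``metrics`` restricts which of the seven statistics are computed (the rest
    are NaN); useful inside permutation loops.
    """
    if degree_convention not in ("E_over_N", "2E_over_N"):
        raise ValueError(f"unknown degree convention {degree_convention!r}")
    wanted = set(METRIC_NAMES if metrics is None else metrics)
    unknown = wanted - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("cannot compute topology metrics of an empty graph")
    e = graph.number_of_edges()
    values: dict[str, float] = {name: math.nan for name in METRIC_NAMES}
    values["all_edges"] = e
    if "largest_subnetwork" in wanted:
        values["largest_subnetwork"] = max(len(c) for c in nx.connected_components(graph))
    if "mean_degree" in wanted:
        values["mean_degree"] = (e if degree_convention == "E_over_N" else 2 * e) / n
    if "closeness_centrality" in wanted:
        cc = nx.closeness_centrality(graph, wf_improved=True)
        values["closeness_centrality"] = sum(cc.values()) / n
    if "mean_shortest_distance" in wanted:
        values["mean_shortest_distance"] = _mean_shortest_distance(graph)
    if "clustering_coefficient" in wanted:
        values["clustering_coefficient"] = nx.average_clustering(graph)
    if "betweenness_centrality" in wanted:
        bc = nx.betweenness_centrality(graph, normalized=True, endpoints=False)
        values["betweenness_centrality"] = sum(bc.values()) / n
    return TopologyMetrics(
        all_edges=int(values["all_edges"]),
        largest_subnetwork=int(values["largest_subnetwork"]) if not math.isnan(values["largest_subnetwork"]) else 0,
        mean_degree=values["mean_degree"],
        closeness_centrality=values["closeness_centrality"],
        mean_shortest_distance=values["mean_shortest_distance"],
        clustering_coefficient=values["clustering_coefficient"],
        betweenness_centrality=values["betweenness_centrality"],
        n_mapped_nodes=n,
    )


def topology_metrics(
    net: nx.Graph,
    genes: GeneSet | Iterable[str],
    degree_convention: str = "E_over_N",
) -> TopologyMetrics:
    """Topology statistics of the subgraph of ``net`` induced by ``genes``.

    Raises
    ------
    ValueError
        If no input gene maps onto the interactome.
    """
    sub = induced_subgraph(net, genes)
    if sub.number_of_nodes() == 0:
        raise ValueError("no input genes map onto the interactome")
    return subgraph_metrics(sub, degree_convention=degree_convention)
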