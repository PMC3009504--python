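"""Pathway-level network container and summary statistics.

A pathway network has pathways as nodes and significant pairwise crosstalk
as undirected edges; each edge carries the observed inter-pathway PPI count,
its empirical p-value and a significance flag.

The reported ``average_degree`` deliberately follows the edges-per-node
convention (edges / nodes) used in this line of work when comparing network
variants; the conventional graph-theoretic mean degree (2·edges / nodes) is
exposed separately as ``mean_degree`` to avoid ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

__all__ = ["PathwayNetwork", "NetworkSummary", "network_summary"]


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    average_degree: float  # edges / nodes, rounded to 1 decimal
    mean_degree: float     # 2*edges / nodes (conventional)


class PathwayNetwork:
    """Undirected pathway graph whose edges passed a significance threshold."""

    def __init__(self, alpha: float = 0.05) -> None:
        self.alpha = float(alpha)
        self._graph = nx.Graph()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int, float, bool]],
        alpha: float = 0.05,
        extra_nodes: Iterable[str] = (),
    ) -> "PathwayNetwork":
        net = cls(alpha=alpha)
        for a, b, count, p, sig in edges:
            net.add_edge(a, b, count=count, p_value=p, significant=sig)
        for n in extra_nodes:
            net._graph.add_node(n)
        return net

    # -- construction ----------------------------------------------------
    def add_edge(self, a: str, b: str, count: int, p_value: float,
                 significant: bool = True) -> None:
        if a == b:
            raise ValueError(f"self-edge {a!r} not allowed in a pathway network")
        self._graph.add_edge(a, b, count=int(count), p_value=float(p_value),
                             significant=bool(significant))

    def add_node(self, name: str) -> None:
        self._graph.add_node(name)

    # -- queries ---------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._graph.edges}

    def iter_edges(self) -> Iterator[tuple[str, str, dict]]:
        """Edges with attributes, endpoints sorted, rows sorted."""
        rows = [(*sorted((a, b)), d) for a, b, d in self._graph.edges(data=True)]
        return iter(sorted(rows, key=lambda r: (r[0], r[1])))

    def degree(self, name: str) -> int:
        if name not in self._graph:
            return 0
        return self._graph.degree[name]

    def degrees(self) -> dict[str, int]:
        return {n: d for n, d in self._graph.degree}

    def has_edge(self, a: str, b: str) -> bool:
        return self._graph.has_edge(a, b)

    def subnetwork(self, keep_nodes: Iterable[str]) -> "PathwayNetwork":
        """Induced sub-network on ``keep_nodes`` (same alpha)."""
        keep = set(keep_nodes)
        out = PathwayNetwork(alpha=self.alpha)
        for a, b, d in self._graph.edges(data=True):
            if a in keep and b in keep:
                out._graph.add_edge(a, b, **d)
        out._graph.add_nodes_from(keep & set(self._graph.nodes))
        return out

    def summary(self) -> NetworkSummary:
        return network_summary(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        if set(self._graph.nodes) != set(other._graph.nodes):
            return False
        if self.edge_set() != other.edge_set():
            return False
        for a, b, d in self._graph.edges(data=True):
            od = other._graph.edges[a, b]
            if (d["count"] != od["count"] or d["significant"] != od["significant"]
                    or abs(d["p_value"] - od["p_value"]) > 1e-12):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PathwayNetwork({self.n_nodes} pathways, {self.n_edges} interactions)"


def network_summary(net: PathwayNetwork) -> NetworkSummary:
    """Node/edge counts plus the edges-per-node average degree.

    An empty network reports 0.0 for both degree statistics.
    """
    n, e = net.n_nodes, net.n_edges
    if n == 0:
        return NetworkSummary(0, 0, 0.0, 0.0)
    return NetworkSummary(n, e, round(e / n, 1), 2 * e / n)
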