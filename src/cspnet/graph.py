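"""Gene-level interaction graphs, pathway gene-set collections and enrichment.

The :class:`PPINetwork` is the universe every later stage works against: it
defines which gene pairs interact (undirected, unweighted), which genes are
eligible for permutation swapping (degree >= 1), and the neighbourhood used to
expand differentially expressed genes into "relevant" genes.  Self-interactions
are accepted on input but stored apart from the simple graph and excluded from
degrees and from all crosstalk counting.

Pathway membership enrichment follows the classic one-sided hypergeometric
(Fisher) test with Bonferroni correction across the tested pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
from scipy import stats

from .io import EdgeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "PathwayCollection",
    "EnrichmentResult",
    "build_ppi_network",
    "neighbours",
    "enrich_pathways",
]


class PPINetwork:
    """Undirected simple gene interaction graph with self-loops set aside.

    Parameters
    ----------
    edges
        Iterable of 2-tuples of gene identifiers.  Reversed duplicates
        collapse; self-pairs are recorded in :attr:`self_loops` and do not
        contribute to degree.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._graph = nx.Graph()
        self.self_loops: set[str] = set()
        for u, v in edges:
            if u == v:
                self.self_loops.add(u)
                self._graph.add_node(u)
            else:
                self._graph.add_edge(u, v)

    # -- basic queries ---------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def genes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._graph.edges}

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as ordered tuples (sorted endpoints, sorted list)."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def degree(self, gene: str) -> int:
        """Number of distinct non-self interaction partners (0 if absent)."""
        if gene not in self._graph:
            return 0
        return self._graph.degree[gene]

    def degrees(self) -> dict[str, int]:
        return {g: d for g, d in self._graph.degree}

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def neighbours(self, genes: Iterable[str]) -> set[str]:
        """Union of interaction partners of ``genes``.

        The inputs themselves are only included when they neighbour each
        other; a gene absent from the network contributes nothing.
        """
        out: set[str] = set()
        for g in genes:
            if g in self._graph:
                out.update(self._graph.neighbors(g))
        return out

    def subgraph_from_edges(self, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        return PPINetwork(edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PPINetwork({self._graph.number_of_nodes()} genes, "
            f"{self.n_edges} interactions, {len(self.self_loops)} self-loops)"
        )


def build_ppi_network(records: Iterable[EdgeRecord]) -> PPINetwork:
    """Assemble a :class:`PPINetwork` from parsed edge records."""
    records = list(records)
    if not records:
        raise ValueError("cannot build a PPI network from zero edge records")
    return PPINetwork((r.gene_a, r.gene_b) for r in records)


def neighbours(net: PPINetwork, genes: Iterable[str]) -> set[str]:
    """Functional alias for :meth:`PPINetwork.neighbours`."""
    return net.neighbours(genes)


class PathwayCollection:
    """Named, possibly overlapping gene sets.

    Mapping-like: iteration yields pathway names in insertion order,
    ``coll[name]`` returns a frozen gene set.
    """

    def __init__(self, pathways: Mapping[str, Iterable[str]]) -> None:
        self._sets: dict[str, frozenset[str]] = {}
        for name, genes in pathways.items():
            gs = frozenset(genes)
            if not gs:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            self._sets[name] = gs

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs
        return out

    def items(self):
        return self._sets.items()

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwayCollection) and self._sets == other._sets

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PathwayCollection({len(self._sets)} pathways, universe {len(self.universe)})"


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's over-representation test against a query gene list."""

    pathway: str
    overlap: int
    p_raw: float
    p_adj: float
    enriched: bool
    pathway_size: int = field(default=0, compare=False)


def enrich_pathways(
    coll: PathwayCollection,
    query: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_pathway_genes: int = 3,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment with Bonferroni correction.

    For each pathway the raw p-value is the upper tail
    ``P(X >= overlap)`` of a hypergeometric draw with population
    ``|universe|``, successes ``|pathway & universe|`` and draws
    ``|query|``.  Pathways with fewer than ``min_pathway_genes`` members in
    the universe are skipped (too unstable to test) and logged.

    Raises
    ------
    ValueError
        If the universe or the query is empty, or the query is not a subset
        of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("enrichment universe is empty")
    if not query:
        raise ValueError("enrichment query gene list is empty")
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query genes absent from universe, e.g. {missing}")

    tested: list[tuple[str, int, int, float]] = []
    for name in coll:
        members = coll[name] & universe
        if len(members) < min_pathway_genes:
            logger.info(
                "pathway %s skipped for enrichment (%d genes in universe < %d)",
                name, len(members), min_pathway_genes,
            )
            continue
        k = len(members & query)
        # P(X >= k) = sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        tested.append((name, k, len(members), min(1.0, p)))

    m = len(tested)
    results = []
    for name, k, size, p in tested:
        p_adj = min(1.0, m * p)
        results.append(
            EnrichmentResult(
                pathway=name, overlap=k, p_raw=p, p_adj=p_adj,
                enriched=p_adj < alpha, pathway_size=size,
            )
        )
    return results
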