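"""Condition-specific pathway networks from single-sample time courses.

With one microarray per timepoint, replicate-based statistics are off the
table; differential expression is called by fold change against the series
baseline (bidirectional, ratio >= threshold in either direction, with a
pseudocount stabilising ratios near zero).  A PPI is *active* at a
timepoint when at least one of its endpoints is differentially expressed
there; the pathway-crosstalk machinery is then re-run on the active-PPI
subgraph to give one pathway network per timepoint.

The immediate PPI neighbours of the DE genes ("relevant genes") are
computed and reported — with single arrays, genes just under the fold
threshold may still matter and their curated interactions argue for
relevance — but by default they do not enter the active-PPI rule, which is
stated purely in terms of DE genes.  Set ``use_relevant_genes=True`` to let
them, as a sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .crosstalk import (
    CountMode,
    PathwayCrosstalkModel,
    SwapInfeasibleError,
    count_pair,
)

logger = logging.getLogger(__name__)
from .graph import PathwayCollection, PPINetwork, enrich_pathways
from .io import ExpressionMatrix
from .network import PathwayNetwork

__all__ = [
    "DECall",
    "ActivePPISet",
    "call_de_genes",
    "active_ppis",
    "PhenotypeSeriesModel",
    "PhenotypeSeriesResults",
    "phenotype_network_series",
]

Restriction = Literal["comprehensive_backbone", "enriched_only", "none"]


@dataclass(frozen=True)
class DECall:
    """Fold-change DE call at one timepoint of one condition."""

    condition: str
    timepoint: str
    de_genes: frozenset[str]
    fc_threshold: float
    relevant_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ActivePPISet:
    condition: str
    timepoint: str
    edges: frozenset[frozenset[str]]


def call_de_genes(
    expr: ExpressionMatrix,
    timepoint: str,
    fc_threshold: float = 2.0,
    pseudocount: float = 1.0,
    ppi: PPINetwork | None = None,
) -> DECall:
    """Bidirectional fold-change DE call versus the baseline column.

    Gene g is DE iff (v_t + eps)/(v_0 + eps) >= threshold or its reciprocal
    is.  When a PPI network is supplied, ``relevant_genes`` is the DE set
    unioned with its immediate neighbours.
    """
    if fc_threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    if timepoint == expr.baseline:
        raise ValueError("cannot call DE of the baseline against itself")
    if timepoint not in expr.values.columns:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; have {list(expr.values.columns)}"
        )
    v_t = expr.values[timepoint].to_numpy(dtype=float) + pseudocount
    v_0 = expr.values[expr.baseline].to_numpy(dtype=float) + pseudocount
    ratio = v_t / v_0
    de_mask = (ratio >= fc_threshold) | (ratio <= 1.0 / fc_threshold)
    de = frozenset(np.asarray(expr.values.index)[de_mask])
    relevant = de
    if ppi is not None:
        relevant = de | ppi.neighbours(de)
    return DECall(
        condition=expr.condition,
        timepoint=timepoint,
        de_genes=de,
        fc_threshold=fc_threshold,
        relevant_genes=frozenset(relevant),
    )


def active_ppis(ppi: PPINetwork, de: DECall, use_relevant_genes: bool = False) -> ActivePPISet:
    """PPI edges with at least one DE endpoint at this timepoint."""
    marked = de.relevant_genes if use_relevant_genes else de.de_genes
    edges = frozenset(
        frozenset((u, v))
        for u, v in ppi.edge_list()
        if u in marked or v in marked
    )
    return ActivePPISet(condition=de.condition, timepoint=de.timepoint, edges=edges)


class PhenotypeSeriesModel:
    """Per-timepoint pathway networks from one condition's time course.

    For each non-baseline timepoint: call DE genes, take the active-PPI
    subgraph, re-run counting + permutation + empirical p on it, keep pairs
    below alpha, then apply the chosen restriction:

    ``comprehensive_backbone`` (default)
        intersect each timepoint's edges with the comprehensive network's;
    ``enriched_only``
        drop pathways not enriched in that timepoint's relevant genes
        before keeping edges (the narrower enriched-pathway baseline);
    ``none``
        keep the per-timepoint networks as-is.  With ``support_filter=True``
        permutation re-testing is skipped entirely and a comprehensive edge
        survives a timepoint iff it has >= 1 active supporting PPI.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        ppi: PPINetwork,
        pathways: PathwayCollection,
        comprehensive: PathwayNetwork | None = None,
        mode: CountMode = "all",
        fc_threshold: float = 2.0,
        pseudocount: float = 1.0,
        restriction: Restriction = "comprehensive_backbone",
        use_relevant_genes: bool = False,
        support_filter: bool = False,
        enrichment_alpha: float = 0.05,
    ) -> None:
        if restriction not in {"comprehensive_backbone", "enriched_only", "none"}:
            raise ValueError(f"unknown restriction {restriction!r}")
        if restriction == "comprehensive_backbone" and comprehensive is None:
            raise ValueError("comprehensive_backbone restriction needs the comprehensive network")
        if support_filter and comprehensive is None:
            raise ValueError("support_filter needs the comprehensive network")
        self.expr = expr
        self.ppi = ppi
        self.pathways = pathways
        self.comprehensive = comprehensive
        self.mode: CountMode = mode
        self.fc_threshold = fc_threshold
        self.pseudocount = pseudocount
        self.restriction: Restriction = restriction
        self.use_relevant_genes = use_relevant_genes
        self.support_filter = support_filter
        self.enrichment_alpha = enrichment_alpha

    def fit(
        self,
        permutations: int = 1000,
        swaps: int = 100_000,
        scheme: str = "uniform",
        seed: int | np.random.SeedSequence | None = None,
        alpha: float = 0.05,
    ) -> "PhenotypeSeriesResults":
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        timepoints = self.expr.non_baseline_timepoints
        children = ss.spawn(len(timepoints))
        de_calls: dict[str, DECall] = {}
        active_sets: dict[str, ActivePPISet] = {}
        networks: dict[str, PathwayNetwork] = {}
        for tp, child in zip(timepoints, children):
            de = call_de_genes(
                self.expr, tp, self.fc_threshold, self.pseudocount, ppi=self.ppi
            )
            act = active_ppis(self.ppi, de, self.use_relevant_genes)
            de_calls[tp] = de
            active_sets[tp] = act
            networks[tp] = self._timepoint_network(
                act, de, permutations, swaps, scheme, child, alpha
            )
        return PhenotypeSeriesResults(
            model=self,
            condition=self.expr.condition,
            timepoints=list(timepoints),
            de_calls=de_calls,
            active_sets=active_sets,
            networks=networks,
            alpha=alpha,
        )

    def _timepoint_network(
        self,
        act: ActivePPISet,
        de: DECall,
        permutations: int,
        swaps: int,
        scheme: str,
        child: np.random.SeedSequence,
        alpha: float,
    ) -> PathwayNetwork:
        active_net = PPINetwork(tuple(sorted(e)) for e in act.edges)
        if self.support_filter:
            assert self.comprehensive is not None
            net = PathwayNetwork(alpha=alpha)
            for a, b, d in self.comprehensive.iter_edges():
                supp = count_pair(
                    active_net, self.pathways[a], self.pathways[b],
                    mode="all", name_a=a, name_b=b,
                )
                if supp >= 1:
                    net.add_edge(a, b, count=supp, p_value=d["p_value"],
                                 significant=True)
            return net
        if active_net.n_edges == 0:
            net = PathwayNetwork(alpha=alpha)
        else:
            model = PathwayCrosstalkModel(active_net, self.pathways, mode=self.mode)
            try:
                res = model.fit(
                    permutations=permutations, swaps=swaps, scheme=scheme,
                    seed=child, alpha=alpha,
                )
            except SwapInfeasibleError:
                # too little activity to build a null at this timepoint:
                # no interaction can be called significant
                logger.warning(
                    "condition %s, timepoint %s: active-PPI graph cannot support "
                    "the permutation null; reporting an empty network",
                    de.condition, de.timepoint,
                )
                return PathwayNetwork(alpha=alpha)
            net = res.network(alpha=alpha)
        if self.restriction == "comprehensive_backbone":
            assert self.comprehensive is not None
            keep = PathwayNetwork(alpha=alpha)
            for a, b, d in net.iter_edges():
                if self.comprehensive.has_edge(a, b):
                    keep.add_edge(a, b, **d)
            net = keep
        elif self.restriction == "enriched_only":
            universe = self.pathways.universe | self.ppi.genes
            query = set(de.relevant_genes) & universe
            if query:
                results = enrich_pathways(
                    self.pathways, query, universe, alpha=self.enrichment_alpha
                )
                enriched = {r.pathway for r in results if r.enriched}
            else:
                enriched = set()
            net = net.subnetwork(enriched)
        return net


@dataclass
class PhenotypeSeriesResults:
    """One condition's per-timepoint pathway networks plus provenance."""

    model: PhenotypeSeriesModel
    condition: str
    timepoints: list[str]
    de_calls: dict[str, DECall]
    active_sets: dict[str, ActivePPISet]
    networks: dict[str, PathwayNetwork]
    alpha: float = 0.05

    def edge_union(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for net in self.networks.values():
            out |= net.edge_set()
        return out

    def presence(self) -> dict[tuple[str, str], list[bool]]:
        """Per-edge boolean presence vector over the timepoint axis."""
        out: dict[tuple[str, str], list[bool]] = {}
        for e in self.edge_union():
            a, b = sorted(e)
            out[(a, b)] = [self.networks[t].has_edge(a, b) for t in self.timepoints]
        return out

    def presence_frame(self) -> pd.DataFrame:
        pres = self.presence()
        return pd.DataFrame(
            [list(v) for v in pres.values()],
            index=pd.MultiIndex.from_tuples(pres.keys(), names=["pathway_a", "pathway_b"]),
            columns=self.timepoints,
        ).sort_index()

    def summary(self) -> str:
        lines = [
            f"Phenotype-specific pathway networks — condition {self.condition!r}",
            "=" * 60,
            f"restriction: {self.model.restriction}   "
            f"fold-change threshold: {self.model.fc_threshold}",
        ]
        for t in self.timepoints:
            s = self.networks[t].summary()
            lines.append(
                f"  {t}: {len(self.de_calls[t].de_genes)} DE genes, "
                f"{len(self.active_sets[t].edges)} active PPIs -> "
                f"{s.n_nodes} pathways / {s.n_edges} interactions"
            )
        return "\n".join(lines)


def phenotype_network_series(
    expr: ExpressionMatrix,
    ppi: PPINetwork,
    coll: PathwayCollection,
    comprehensive: PathwayNetwork | None = None,
    restriction: Restriction = "comprehensive_backbone",
    mode: CountMode = "all",
    fc_threshold: float = 2.0,
    permutations: int = 1000,
    swaps: int = 100_000,
    scheme: str = "uniform",
    seed: int | np.random.SeedSequence | None = None,
    alpha: float = 0.05,
    **kwargs,
) -> PhenotypeSeriesResults:
    """Functional wrapper around :class:`PhenotypeSeriesModel`."""
    model = PhenotypeSeriesModel(
        expr, ppi, coll, comprehensive=comprehensive, mode=mode,
        fc_threshold=fc_threshold, restriction=restriction, **kwargs,
    )
    return model.fit(
        permutations=permutations, swaps=swaps, scheme=scheme, seed=seed, alpha=alpha
    )
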