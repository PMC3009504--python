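"""Static and dynamic characteristic sub pathway network (CSPN) detection.

Given phenotype-specific pathway-network series for two or more conditions
(e.g. two cytokine stimulations of the same cell system):

* the **static core** is the exact intersection of edges present at every
  timepoint of every condition; the **static CSPN** keeps its highly
  connected pathways — those whose degree within the core *and* within the
  comprehensive network both reach a degree quantile;
* the **dynamic CSPN** collects interactions that alter obviously over
  time — presence vectors flipping between timepoints — among pathways of
  relatively low comprehensive degree.

"Alters obviously" is scored per condition as ``min(k, T-k) / floor(T/2)``
where k is the number of timepoints at which the edge is present out of T:
0 for always/never present, 1 for a maximally balanced on/off pattern.

The detectors report candidates by these objective criteria; curation
against prior biological knowledge is deliberately left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import PathwayNetwork
from .phenotype import PhenotypeSeriesResults

__all__ = [
    "CSPNResult",
    "SeriesSnapshot",
    "static_core",
    "detect_static_cspn",
    "edge_variability",
    "detect_dynamic_cspn",
    "detect_cspn",
    "compare_dynamic_timepoints",
]

Edge = tuple[str, str]


@dataclass
class SeriesSnapshot:
    """Minimal phenotype-series view (e.g. re-read from disk) for detection.

    Interchangeable with :class:`~cspnet.phenotype.PhenotypeSeriesResults`
    wherever the detectors only need the per-timepoint networks.
    """

    condition: str
    timepoints: list[str]
    networks: dict[str, PathwayNetwork]

    def edge_union(self) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for net in self.networks.values():
            out |= net.edge_set()
        return out


def _norm(edge) -> Edge:
    a, b = sorted(edge)
    return (a, b)


@dataclass
class DynamicFragment:
    """Per-condition dynamic CSPN material."""

    candidate_pathways: set[str]
    edges: set[Edge]
    # per condition: edge -> presence vector over that condition's timepoints
    presence: dict[str, dict[Edge, list[bool]]]
    timepoints: dict[str, list[str]]


@dataclass
class CSPNResult:
    """Static and dynamic characteristic sub pathway networks.

    Invariants: every static edge is present at every timepoint of every
    input condition; every dynamic edge's presence vector is non-constant
    in at least one condition; the two edge sets are disjoint.
    """

    static_nodes: set[str]
    static_edges: set[Edge]
    dynamic: DynamicFragment
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Characteristic sub pathway networks",
            "=" * 50,
            f"static CSPN: {len(self.static_nodes)} pathways, "
            f"{len(self.static_edges)} persistent interactions",
            f"dynamic CSPN: {len(self.dynamic.candidate_pathways)} pathways, "
            f"{len(self.dynamic.edges)} time-varying interactions",
            f"params: {self.params}",
        ]
        for e in sorted(self.static_edges):
            lines.append(f"  static   {e[0]} -- {e[1]}")
        for e in sorted(self.dynamic.edges):
            pat = {
                cond: "".join(
                    "1" if x else "0" for x in self.dynamic.presence[cond].get(e, [])
                )
                for cond in sorted(self.dynamic.presence)
            }
            lines.append(f"  dynamic  {e[0]} -- {e[1]}  presence {pat}")
        return "\n".join(lines)


def static_core(
    series_list: Sequence[PhenotypeSeriesResults],
) -> tuple[set[str], set[Edge]]:
    """Edges present at every timepoint of every condition, plus their nodes."""
    if not series_list:
        raise ValueError("need at least one phenotype network series")
    core: set[frozenset[str]] | None = None
    for series in series_list:
        if not series.timepoints:
            raise ValueError(f"condition {series.condition!r} has no timepoints")
        for tp in series.timepoints:
            edges = series.networks[tp].edge_set()
            core = edges if core is None else core & edges
    assert core is not None
    edges = {_norm(e) for e in core}
    nodes = {n for e in edges for n in e}
    return nodes, edges


def _degree_in(edges: set[Edge], node: str) -> int:
    return sum(1 for e in edges if node in e)


def detect_static_cspn(
    core: tuple[set[str], set[Edge]],
    comprehensive: PathwayNetwork,
    hub_quantile: float = 0.75,
    min_comprehensive_degree: int | None = None,
) -> tuple[set[str], set[Edge]]:
    """Keep the highly connected part of the static core.

    A pathway survives when its degree inside the core reaches the
    ``hub_quantile`` of core degrees AND its comprehensive-network degree
    reaches the same quantile of comprehensive degrees (or the absolute
    ``min_comprehensive_degree`` override, when given).  The induced edges
    are kept.
    """
    nodes, edges = core
    if not nodes:
        return set(), set()
    core_deg = {n: _degree_in(edges, n) for n in nodes}
    q_core = float(np.quantile(list(core_deg.values()), hub_quantile))
    comp_degs = list(comprehensive.degrees().values()) or [0]
    if min_comprehensive_degree is not None:
        q_comp = float(min_comprehensive_degree)
    else:
        q_comp = float(np.quantile(comp_degs, hub_quantile))
    keep = {
        n for n in nodes
        if core_deg[n] >= q_core and comprehensive.degree(n) >= q_comp
    }
    kept_edges = {e for e in edges if e[0] in keep and e[1] in keep}
    return keep, kept_edges


def edge_variability(series: PhenotypeSeriesResults, edge) -> float:
    """Normalised presence-flip score in [0, 1] for one edge in one condition."""
    T = len(series.timepoints)
    if T < 2:
        raise ValueError("edge variability needs at least two timepoints")
    a, b = _norm(edge)
    k = sum(1 for tp in series.timepoints if series.networks[tp].has_edge(a, b))
    return min(k, T - k) / (T // 2)


def detect_dynamic_cspn(
    series_list: Sequence[PhenotypeSeriesResults],
    comprehensive: PathwayNetwork,
    var_threshold: float = 0.5,
    low_degree_quantile: float = 0.5,
    max_comprehensive_degree: int | None = None,
) -> DynamicFragment:
    """Time-varying interactions among low-degree pathways.

    Candidate edges reach variability >= ``var_threshold`` in at least one
    condition; candidate pathways are endpoints of candidate edges whose
    comprehensive degree is <= the ``low_degree_quantile`` of comprehensive
    degrees (or the absolute override).  The fragment keeps candidate edges
    joining two candidate pathways, with per-condition presence vectors.
    """
    if not series_list:
        raise ValueError("need at least one phenotype network series")
    all_edges: set[Edge] = set()
    for series in series_list:
        all_edges |= {_norm(e) for e in series.edge_union()}
    candidates = {
        e for e in all_edges
        if any(edge_variability(s, e) >= var_threshold for s in series_list)
    }
    comp_degs = list(comprehensive.degrees().values()) or [0]
    if max_comprehensive_degree is not None:
        q_low = float(max_comprehensive_degree)
    else:
        q_low = float(np.quantile(comp_degs, low_degree_quantile))
    cand_nodes = {
        n for e in candidates for n in e if comprehensive.degree(n) <= q_low
    }
    kept = {e for e in candidates if e[0] in cand_nodes and e[1] in cand_nodes}
    presence = {
        s.condition: {
            e: [s.networks[tp].has_edge(*e) for tp in s.timepoints] for e in kept
        }
        for s in series_list
    }
    timepoints = {s.condition: list(s.timepoints) for s in series_list}
    return DynamicFragment(
        candidate_pathways=cand_nodes,
        edges=kept,
        presence=presence,
        timepoints=timepoints,
    )


def detect_cspn(
    series_list: Sequence[PhenotypeSeriesResults],
    comprehensive: PathwayNetwork,
    hub_quantile: float = 0.75,
    low_degree_quantile: float = 0.5,
    var_threshold: float = 0.5,
    min_comprehensive_degree: int | None = None,
    max_comprehensive_degree: int | None = None,
) -> CSPNResult:
    """Full static + dynamic detection with disjointness enforced."""
    core = static_core(series_list)
    s_nodes, s_edges = detect_static_cspn(
        core, comprehensive, hub_quantile, min_comprehensive_degree
    )
    dyn = detect_dynamic_cspn(
        series_list, comprehensive, var_threshold, low_degree_quantile,
        max_comprehensive_degree,
    )
    # a static (always-present) edge can only be a dynamic candidate when
    # var_threshold == 0; enforce the disjointness invariant regardless
    dyn.edges -= core[1]
    for cond in dyn.presence:
        dyn.presence[cond] = {e: v for e, v in dyn.presence[cond].items() if e in dyn.edges}
    return CSPNResult(
        static_nodes=s_nodes,
        static_edges=s_edges,
        dynamic=dyn,
        params={
            "hub_quantile": hub_quantile,
            "low_degree_quantile": low_degree_quantile,
            "var_threshold": var_threshold,
            "min_comprehensive_degree": min_comprehensive_degree,
            "max_comprehensive_degree": max_comprehensive_degree,
        },
    )


def compare_dynamic_timepoints(
    result: CSPNResult,
) -> dict[str, dict[str, list[Edge]]]:
    """Per-condition, per-timepoint snapshots of the dynamic CSPN edges."""
    out: dict[str, dict[str, list[Edge]]] = {}
    for cond, pres in result.dynamic.presence.items():
        tps = result.dynamic.timepoints[cond]
        out[cond] = {
            tp: sorted(e for e, vec in pres.items() if vec[i])
            for i, tp in enumerate(tps)
        }
    return out
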