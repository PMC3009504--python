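"""Readers and writers for the external formats the pipeline touches.

Supported inputs: two-column (or more) PPI edge TSV, Cytoscape SIF,
Broad-dialect GMT gene sets, and expression TSV (gene rows x timepoint
columns with a header).  Outputs: pathway-network TSV/GraphML and the
three-column edge-by-timepoint presence table.

Gene and pathway identifiers are opaque case-sensitive strings; no
identifier mapping is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import PathwayNetwork

__all__ = [
    "EdgeRecord",
    "GeneSetRecord",
    "ExpressionMatrix",
    "ParseError",
    "read_ppi_edges",
    "read_gmt",
    "read_expression",
    "write_pathway_network",
    "read_pathway_network",
    "write_timepoint_table",
    "read_timepoint_table",
    "write_enrichment_table",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected interaction; equal to its reverse."""

    gene_a: str
    gene_b: str
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("edge endpoints must be non-empty gene identifiers")
        # canonical endpoint order so {A,B} == {B,A}
        if self.gene_b < self.gene_a:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def is_self_edge(self) -> bool:
        return self.gene_a == self.gene_b


@dataclass(frozen=True)
class GeneSetRecord:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class ExpressionMatrix:
    """Genes x timepoints intensity matrix for one condition.

    One sample per timepoint; exactly one column is the designated baseline.
    """

    values: pd.DataFrame          # index: genes, columns: timepoint labels
    baseline: str
    condition: str

    def __post_init__(self) -> None:
        if self.baseline not in self.values.columns:
            raise ValueError(
                f"baseline label {self.baseline!r} not among timepoints "
                f"{list(self.values.columns)}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression intensities must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene rows must be collapsed before construction")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def non_baseline_timepoints(self) -> list[str]:
        return [t for t in self.values.columns if t != self.baseline]


def _dedupe_edges(records: Iterable[EdgeRecord]) -> list[EdgeRecord]:
    seen: set[tuple[str, str]] = set()
    out: list[EdgeRecord] = []
    for r in records:
        key = (r.gene_a, r.gene_b)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def read_ppi_edges(path: str | Path, dialect: str = "tsv") -> list[EdgeRecord]:
    """Read undirected PPI edges from a TSV or SIF file.

    TSV lines have >= 2 tab-separated fields (gene_a, gene_b[, source...]).
    SIF lines are ``node relation target1 [target2 ...]`` and expand one line
    to one edge per target.  Reversed and repeated edges collapse; self-edges
    are retained (flag via :attr:`EdgeRecord.is_self_edge`).
    """
    path = Path(path)
    if dialect not in {"tsv", "sif"}:
        raise ValueError(f"unknown PPI dialect {dialect!r}; use 'tsv' or 'sif'")
    records: list[EdgeRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "tsv":
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ParseError(
                        f"{path}:{lineno}: expected >=2 tab-separated gene fields, "
                        f"got {line!r}"
                    )
                src = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
                records.append(EdgeRecord(fields[0].strip(), fields[1].strip(), src))
            else:  # sif: whitespace-delimited, one-to-many
                fields = line.split()
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF line needs 'source relation target...', "
                        f"got {line!r}"
                    )
                src_gene, relation, *targets = fields
                for t in targets:
                    records.append(EdgeRecord(src_gene, t, relation))
    if not records:
        raise ParseError(f"{path}: no edges found")
    return _dedupe_edges(records)


def read_gmt(path: str | Path) -> list[GeneSetRecord]:
    """Read Broad-dialect GMT: name, description, >=1 gene, tab-separated."""
    path = Path(path)
    records: list[GeneSetRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            records.append(GeneSetRecord(name, desc, frozenset(genes)))
    if not records:
        raise ParseError(f"{path}: no gene sets found")
    return records


def read_expression(
    path: str | Path, baseline_label: str, condition: str
) -> ExpressionMatrix:
    """Read a genes x timepoints TSV; duplicate gene rows collapse by max.

    Single-sample arrays offer no replicate averaging, so repeated rows for
    one gene (e.g. multiple probes) collapse to the per-cell maximum.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    if baseline_label not in df.columns:
        raise ParseError(
            f"{path}: baseline label {baseline_label!r} not among columns "
            f"{list(df.columns)}"
        )
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression value")
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(values=df, baseline=baseline_label, condition=condition)


_NET_COLUMNS = ["pathway_a", "pathway_b", "count", "p_value", "significant"]


def write_pathway_network(
    net: PathwayNetwork, path: str | Path, format: str = "tsv"
) -> None:
    """Serialise a pathway network as TSV (canonical) or GraphML.

    TSV columns: pathway_a, pathway_b, count, p_value, significant; one row
    per edge, endpoints and rows sorted so output is deterministic.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(_NET_COLUMNS) + "\n")
            for a, b, d in net.iter_edges():
                fh.write(
                    f"{a}\t{b}\t{d['count']}\t{d['p_value']!r}\t{d['significant']}\n"
                )
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(net.nodes))
        for a, b, d in net.iter_edges():
            g.add_edge(a, b, **d)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}; use 'tsv' or 'graphml'")


def read_pathway_network(
    path: str | Path, format: str = "tsv", alpha: float = 0.05
) -> PathwayNetwork:
    """Inverse of :func:`write_pathway_network`."""
    path = Path(path)
    net = PathwayNetwork(alpha=alpha)
    if format == "tsv":
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _NET_COLUMNS:
                raise ParseError(f"{path}: unexpected header {header}")
            for lineno, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 fields")
                a, b, count, p, sig = fields
                net.add_edge(a, b, count=int(count), p_value=float(p),
                             significant=sig == "True")
    elif format == "graphml":
        g = nx.read_graphml(path)
        for n in g.nodes:
            net.add_node(n)
        for a, b, d in g.edges(data=True):
            net.add_edge(a, b, count=int(d["count"]), p_value=float(d["p_value"]),
                         significant=bool(d["significant"]))
    else:
        raise ValueError(f"unknown network format {format!r}")
    return net


def write_timepoint_table(
    presence: Mapping[tuple[str, str], Sequence[bool]],
    path: str | Path,
    timepoints: Sequence[str],
) -> None:
    """Write per-edge timepoint presence as three TSV columns.

    Columns: pathway_a, pathway_b, comma-joined labels of the timepoints at
    which the interaction exists.  Edges present nowhere are omitted.
    """
    path = Path(path)
    T = len(timepoints)
    rows = []
    for (a, b), vec in presence.items():
        if len(vec) != T:
            raise ValueError(
                f"edge ({a},{b}) has a {len(vec)}-long presence vector but "
                f"{T} timepoints were given"
            )
        labels = [t for t, present in zip(timepoints, vec) if present]
        if labels:
            x, y = sorted((a, b))
            rows.append((x, y, ",".join(labels)))
    rows.sort()
    with path.open("w") as fh:
        fh.write("pathway_a\tpathway_b\ttimepoints\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_timepoint_table(
    path: str | Path, timepoints: Sequence[str]
) -> dict[tuple[str, str], list[bool]]:
    """Inverse of :func:`write_timepoint_table` (omitted edges stay absent)."""
    path = Path(path)
    out: dict[tuple[str, str], list[bool]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["pathway_a", "pathway_b", "timepoints"]:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            a, b, labels = fields
            present = set(labels.split(","))
            unknown = present - set(timepoints)
            if unknown:
                raise ParseError(f"{path}:{lineno}: unknown timepoints {sorted(unknown)}")
            out[(a, b)] = [t in present for t in timepoints]
    return out


def write_enrichment_table(results, path: str | Path) -> None:
    """TSV export of enrichment results (pathway, overlap, p_raw, p_adj, enriched)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pathway\toverlap\tp_raw\tp_adj\tenriched\n")
        for r in results:
            fh.write(f"{r.pathway}\t{r.overlap}\t{r.p_raw!r}\t{r.p_adj!r}\t{r.enriched}\n")
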