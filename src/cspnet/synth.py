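"""Seeded synthetic data: PPI graphs, overlapping pathway collections and
time-course expression with planted crosstalk.

The generators emulate the shape of the real inputs this kind of analysis
runs on — a sparse curated interactome over the order of 10^4 genes, a few
dozen overlapping pathway gene sets, and per-condition single-sample
time-course intensity matrices with a baseline column — scaled down so a
full analysis runs on a desktop.  Planted structure gives every stage a
ground truth:

* extra PPI edges between the exclusive genes of chosen pathway pairs plant
  crosstalk on top of an Erdős–Rényi background;
* a *persistent* schedule up-regulates the genes supporting a planted pair
  at every non-baseline timepoint (static, hub-like interactions), a
  *transient* schedule only at chosen timepoints (dynamic interactions);
* multiplicative log-normal noise on intensities models array noise.

Defaults (the generator's study conditions, chosen once): 1200 genes at
background edge density 0.003, 30 pathways of 20–40 genes with ~10%
chaining overlap, a persistent 4-clique of hub pathways plus three
transient low-degree pairs (30 planted cross edges each), two conditions,
four non-baseline timepoints, baseline intensity 100, fold-change signal 4,
log-normal noise sigma 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .graph import PathwayCollection, PPINetwork
from .io import ExpressionMatrix

import pandas as pd

__all__ = [
    "PlantedPair",
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "make_pathways",
    "make_ppi",
    "make_timecourse",
    "generate_dataset",
    "power_config",
    "calibration_config",
    "recovery_config",
]

Pair = tuple[str, str]

PERSISTENT = "persistent"


@dataclass(frozen=True)
class PlantedPair:
    """One pathway pair given extra cross edges and an activity schedule."""

    pathway_a: str
    pathway_b: str
    n_cross_edges: int = 30
    #: "persistent" or the tuple of non-baseline timepoint labels at which
    #: the supporting genes are up-regulated
    schedule: str | tuple[str, ...] = PERSISTENT

    @property
    def pair(self) -> Pair:
        a, b = sorted((self.pathway_a, self.pathway_b))
        return (a, b)

    @property
    def is_persistent(self) -> bool:
        return self.schedule == PERSISTENT


def _default_planted(n_pathways: int, timepoints: Sequence[str]) -> tuple[PlantedPair, ...]:
    if n_pathways < 12 or len(timepoints) < 4:
        raise ValueError(
            "default planted structure needs >=12 pathways and >=4 non-baseline "
            "timepoints; pass planted_pairs explicitly for smaller designs"
        )
    names = [f"P{i + 1:02d}" for i in range(n_pathways)]
    planted: list[PlantedPair] = []
    # persistent hub clique on the first four pathways
    for i in range(4):
        for j in range(i + 1, 4):
            planted.append(PlantedPair(names[i], names[j]))
    # transient low-degree pairs, each active at two of four timepoints
    t = list(timepoints)
    planted.append(PlantedPair(names[4], names[5], schedule=(t[1], t[3])))
    planted.append(PlantedPair(names[6], names[7], schedule=(t[0], t[1])))
    planted.append(PlantedPair(names[8], names[9], schedule=(t[2], t[3])))
    # structural-only filler chain over the remaining pathways: crosstalk in
    # the interactome with no expression events, so the comprehensive network
    # has a graded degree distribution like a real curated one
    for i in range(10, n_pathways - 1):
        planted.append(PlantedPair(names[i], names[i + 1], schedule=()))
    return tuple(planted)


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 1200
    edge_density: float = 0.003
    n_pathways: int = 30
    size_range: tuple[int, int] = (20, 40)
    overlap_fraction: float = 0.1
    planted_pairs: tuple[PlantedPair, ...] | None = None
    n_timepoints: int = 4          # non-baseline timepoints per condition
    conditions: tuple[str, ...] = ("cond1", "cond2")
    baseline_intensity: float = 100.0
    fc_signal: float = 4.0
    noise_sd: float = 0.2          # sigma of the log-normal multiplicative noise
    #: cap background cross-edge counts of pairs touching expression-scheduled
    #: pathways at mean + cap_sd*sqrt(mean); None disables.  This keeps the
    #: planted schedule the only persistent signal around those pathways, so
    #: ground-truth recovery is well-posed; pairs away from the scheduled
    #: pathways keep their natural background fluctuations.
    background_cross_cap_sd: float | None = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_pathways < 2 or self.n_timepoints < 1:
            raise ValueError("counts must be positive (>=2 genes/pathways)")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not (0 <= self.edge_density <= 1):
            raise ValueError(
                f"edge density {self.edge_density} infeasible for a simple graph"
            )
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError("invalid pathway size range")
        if self.fc_signal <= 1:
            raise ValueError("fc_signal must exceed 1 (it must be detectable)")

    @property
    def pathway_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pathways)]

    @property
    def timepoints(self) -> list[str]:
        """Baseline label followed by the non-baseline labels."""
        return [f"t{i}" for i in range(self.n_timepoints + 1)]

    @property
    def baseline(self) -> str:
        return "t0"

    def resolved_planted(self) -> tuple[PlantedPair, ...]:
        if self.planted_pairs is not None:
            return self.planted_pairs
        return _default_planted(self.n_pathways, self.timepoints[1:])


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    planted_edges: dict[Pair, set[frozenset[str]]] = field(default_factory=dict)
    supporting_genes: dict[Pair, set[str]] = field(default_factory=dict)
    persistent_pairs: set[Pair] = field(default_factory=set)
    transient_pairs: dict[Pair, tuple[str, ...]] = field(default_factory=dict)
    #: structural crosstalk with no expression schedule
    filler_pairs: set[Pair] = field(default_factory=set)
    adjacent_overlaps: dict[Pair, int] = field(default_factory=dict)
    background_edge_count: int = 0
    #: condition -> timepoint -> genes that were up-regulated there
    de_genes: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def planted_pairs(self) -> set[Pair]:
        return set(self.planted_edges)


@dataclass
class SynthDataset:
    config: SynthConfig
    ppi: PPINetwork
    pathways: PathwayCollection
    expression: dict[str, ExpressionMatrix]
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def make_pathways(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[PathwayCollection, GroundTruth]:
    """Overlapping gene sets chained so adjacent pathways share genes.

    Pathway i draws ~overlap_fraction of its size from pathway i-1 and the
    rest from genes not yet assigned to any pathway, so non-adjacent
    pathways are disjoint and the exclusive parts stay exclusive.
    """
    genes = _gene_names(config.n_genes)
    unused = list(genes)
    lo, hi = config.size_range
    truth = GroundTruth()
    sets: dict[str, frozenset[str]] = {}
    prev: list[str] = []
    for name in config.pathway_names:
        size = int(rng.integers(lo, hi + 1))
        n_shared = int(round(config.overlap_fraction * size)) if prev else 0
        n_shared = min(n_shared, len(prev))
        shared = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
        n_new = size - n_shared
        if n_new > len(unused):
            raise ValueError(
                f"gene pool exhausted at pathway {name}: need {n_new} fresh genes, "
                f"{len(unused)} left; increase n_genes or shrink pathways"
            )
        pick = rng.choice(len(unused), size=n_new, replace=False)
        fresh = [unused[i] for i in sorted(pick)]
        for i in sorted(pick, reverse=True):
            unused.pop(i)
        members = sorted(set(shared) | set(fresh))
        sets[name] = frozenset(members)
        if prev:
            prev_name = list(sets)[-2]
            pair = tuple(sorted((prev_name, name)))
            truth.adjacent_overlaps[pair] = len(sets[prev_name] & sets[name])
        prev = members
    return PathwayCollection(sets), truth


def make_ppi(
    config: SynthConfig,
    coll: PathwayCollection,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[PPINetwork, GroundTruth]:
    """Erdős–Rényi background plus planted cross edges for each planted pair.

    Planted edges join genes belonging to *only* one pathway of the pair
    and to no other pathway in the collection.  Sole membership keeps the
    schedules of different planted pairs decoupled: a supporting gene is
    up-regulated exactly when its own pair is scheduled, and a planted edge
    can never double as crosstalk of a third pathway.
    """
    truth = truth if truth is not None else GroundTruth()
    genes = _gene_names(config.n_genes)
    n = config.n_genes
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.edge_density
    edges: set[frozenset[str]] = {
        frozenset((genes[i], genes[j])) for i, j in zip(iu[mask], ju[mask])
    }
    truth.background_edge_count = len(edges)

    n_memberships: dict[str, int] = {}
    for name in coll:
        for g in coll[name]:
            n_memberships[g] = n_memberships.get(g, 0) + 1

    for pp in config.resolved_planted():
        if pp.pathway_a not in coll or pp.pathway_b not in coll:
            raise ValueError(f"planted pair references unknown pathway: {pp.pair}")
        A = coll[pp.pathway_a]
        B = coll[pp.pathway_b]
        left = sorted(g for g in A if n_memberships[g] == 1)
        right = sorted(g for g in B if n_memberships[g] == 1)
        possible = [
            frozenset((u, v)) for u in left for v in right
            if frozenset((u, v)) not in edges
        ]
        if len(possible) < pp.n_cross_edges:
            raise ValueError(
                f"cannot plant {pp.n_cross_edges} cross edges for {pp.pair}: "
                f"only {len(possible)} free exclusive pairs"
            )
        pick = rng.choice(len(possible), size=pp.n_cross_edges, replace=False)
        chosen = {possible[i] for i in pick}
        edges |= chosen
        pair = pp.pair
        truth.planted_edges.setdefault(pair, set()).update(chosen)
        truth.supporting_genes.setdefault(pair, set()).update(
            g for e in chosen for g in e
        )
        if pp.is_persistent:
            truth.persistent_pairs.add(pair)
        elif pp.schedule:
            truth.transient_pairs[pair] = tuple(pp.schedule)
        else:
            truth.filler_pairs.add(pair)

    if config.background_cross_cap_sd is not None:
        _cap_background_cross(config, coll, edges, truth, rng)

    net = PPINetwork(tuple(sorted(e)) for e in edges)
    return net, truth


def _cap_background_cross(
    config: SynthConfig,
    coll: PathwayCollection,
    edges: set[frozenset[str]],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    """Trim background cross edges of pairs touching scheduled pathways.

    Pairs with one endpoint among the expression-scheduled pathways have
    their *background* (non-planted) cross-edge count capped at
    mean + cap_sd*sqrt(mean) of the Erdős–Rényi expectation, so no such
    pair carries an accidental persistent surplus that would rival the
    planted signal.
    """
    scheduled: set[str] = set()
    for pair in truth.persistent_pairs | set(truth.transient_pairs):
        scheduled.update(pair)
    if not scheduled:
        return
    planted_all: set[frozenset[str]] = set()
    for es in truth.planted_edges.values():
        planted_all |= es
    names = coll.names
    capped_pairs = sorted(
        tuple(sorted((a, b)))
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if (a in scheduled or b in scheduled)
    )
    membership: dict[str, set[str]] = {}
    for name in coll:
        for g in coll[name]:
            membership.setdefault(g, set()).add(name)
    buckets: dict[Pair, list[frozenset[str]]] = {p: [] for p in capped_pairs}
    capset = set(capped_pairs)
    for e in edges:
        if e in planted_all or len(e) != 2:
            continue
        u, v = tuple(e)
        pu = membership.get(u)
        pv = membership.get(v)
        if not pu or not pv:
            continue
        for P in pu:
            for Q in pv:
                if P == Q:
                    continue
                pr = (P, Q) if P < Q else (Q, P)
                if pr in capset:
                    buckets[pr].append(e)
    removed: set[frozenset[str]] = set()
    for pr in capped_pairs:
        lam = config.edge_density * len(coll[pr[0]]) * len(coll[pr[1]])
        cap = int(np.ceil(lam + config.background_cross_cap_sd * np.sqrt(max(lam, 1e-12))))
        alive = [e for e in set(buckets[pr]) if e not in removed]
        excess = len(alive) - cap
        if excess > 0:
            alive.sort(key=sorted)
            pick = rng.choice(len(alive), size=excess, replace=False)
            removed.update(alive[i] for i in pick)
    edges -= removed
    truth.background_edge_count -= len(removed)


def make_timecourse(
    config: SynthConfig,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> dict[str, ExpressionMatrix]:
    """One expression matrix per condition with planted fold-change events.

    All intensities are ``baseline_intensity`` times log-normal noise; genes
    supporting a planted pair are additionally multiplied by ``fc_signal``
    at the scheduled timepoints (every non-baseline timepoint for
    persistent pairs).  The realised up-regulation sets are recorded in
    ``truth.de_genes`` per condition and timepoint.
    """
    genes = _gene_names(config.n_genes)
    tps = config.timepoints
    non_base = tps[1:]
    planted = config.resolved_planted()
    for pp in planted:
        if not pp.is_persistent:
            unknown = set(pp.schedule) - set(non_base)
            if unknown:
                raise ValueError(
                    f"planted pair {pp.pair} schedules unknown timepoints {sorted(unknown)}"
                )
    out: dict[str, ExpressionMatrix] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    for cond in config.conditions:
        if config.noise_sd > 0:
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=(len(genes), len(tps))))
        else:
            noise = np.ones((len(genes), len(tps)))
        values = config.baseline_intensity * noise
        de_by_tp: dict[str, set[str]] = {t: set() for t in non_base}
        for pp in planted:
            sched = non_base if pp.is_persistent else list(pp.schedule)
            for t in sched:
                de_by_tp[t] |= truth.supporting_genes[pp.pair]
        for j, t in enumerate(tps):
            if t == config.baseline:
                continue
            rows = [gene_index[g] for g in sorted(de_by_tp[t])]
            values[rows, j] *= config.fc_signal
        truth.de_genes[cond] = de_by_tp
        df = pd.DataFrame(values, index=genes, columns=tps)
        out[cond] = ExpressionMatrix(values=df, baseline=config.baseline, condition=cond)
    return out


def power_config(n_cross_edges: int = 30) -> SynthConfig:
    """Crosstalk-power study condition: few planted pairs, raw background.

    Three well-separated persistent pairs over the default-size gene set,
    no noise and no background capping, so planted pairs test detection
    power while the many unplanted pairs probe the null's nominal type-I
    rate.  The background is denser than the recovery defaults (0.02) so
    pair counts are fine-grained: an empirical p on heavily tied small
    counts is super-uniform and the achieved level would sit well below
    alpha.
    """
    planted = (
        PlantedPair("P01", "P02", n_cross_edges=n_cross_edges),
        PlantedPair("P07", "P15", n_cross_edges=n_cross_edges),
        PlantedPair("P20", "P28", n_cross_edges=n_cross_edges),
    )
    return SynthConfig(
        planted_pairs=planted,
        edge_density=0.02,
        noise_sd=0.0,
        background_cross_cap_sd=None,
    )


def recovery_config() -> SynthConfig:
    """Scaled-down CSPN-recovery study condition for replicated runs.

    Same planted architecture as the full defaults (persistent hub clique,
    three transient pairs, structural filler chain) on a smaller gene set,
    so one full two-condition analysis takes seconds and recovery can be
    replicated over many seeds.
    """
    return SynthConfig(
        n_genes=600,
        edge_density=0.005,
        n_pathways=16,
        size_range=(18, 28),
    )


def calibration_config() -> SynthConfig:
    """Null-calibration study condition: no planted structure at all.

    A fixed moderate Erdős–Rényi graph with ten disjoint 25-gene pathways
    assigned independently of the edges, so every pair is null and the
    fraction of pairs below any alpha should sit at alpha.
    """
    return SynthConfig(
        n_genes=300,
        edge_density=0.02,
        n_pathways=10,
        size_range=(25, 25),
        overlap_fraction=0.0,
        planted_pairs=(),
        noise_sd=0.0,
        background_cross_cap_sd=None,
    )


def generate_dataset(
    config: SynthConfig | None = None, seed: int | None = None
) -> SynthDataset:
    """Generate a full, internally consistent synthetic dataset.

    ``seed`` overrides ``config.seed``; a fixed seed gives bit-identical
    output across runs.
    """
    config = config if config is not None else SynthConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    coll, truth = make_pathways(config, rng)
    ppi, truth = make_ppi(config, coll, rng, truth)
    expression = make_timecourse(config, rng, truth)
    return SynthDataset(
        config=config, ppi=ppi, pathways=coll, expression=expression, truth=truth
    )
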