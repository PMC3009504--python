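"""Pathway-pair crosstalk counting, the gene-exchange permutation null, and
empirical significance.

The statistic for a pathway pair (A, B) is the number of distinct PPI edges
running between them.  A gene shared by both pathways is treated as a member
of each side — an edge u-v with u in the overlap still crosses the pair —
but the *sharing relation itself* (u == v) is never an interaction, and PPI
self-loops are never counted.  Three counting modes are offered:

``all``
    every distinct edge {u, v}, u != v, with one endpoint in A and the
    other in B (either orientation; each PPI edge counts at most once);
``no_shared``
    the same restricted to u in A\\B and v in B\\A — crosstalk purely
    between the exclusive parts;
``shared_only``
    the overlap size |A & B| (component sharing as the sole crosstalk
    mechanism; no PPI edges involved).

Significance comes from a gene-exchange null: pathway labels are rewired by
repeatedly swapping two distinct genes between two different pathways, both
genes required to interact with at least one gene, preserving every pathway
size and the global membership multiset.  The observed count is compared
against R such permuted collections; the empirical p-value is the fraction
of permutations whose count reaches the observed one.

The :class:`PathwayCrosstalkModel` / :class:`CrosstalkResults` pair wraps
this machinery statsmodels-style: build the model from the PPI network and
the pathway collection, ``fit`` runs the permutations, the results object
carries counts, p-values, a summary table and the significant-edge network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .graph import PathwayCollection, PPINetwork
from .network import PathwayNetwork, NetworkSummary, network_summary

__all__ = [
    "CountMode",
    "SwapInfeasibleError",
    "count_pair",
    "count_all_pairs",
    "permute_collection",
    "null_distribution",
    "empirical_p",
    "build_pathway_network",
    "network_summary",
    "NetworkSummary",
    "PathwayCrosstalkModel",
    "CrosstalkResults",
]

CountMode = Literal["all", "no_shared", "shared_only"]
_MODES = ("all", "no_shared", "shared_only")


class SwapInfeasibleError(RuntimeError):
    """No valid gene exchange exists (or none found within the proposal cap)."""

Pair = tuple[str, str]


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"unknown counting mode {mode!r}; use one of {_MODES}")


def count_pair(
    ppi: PPINetwork,
    set_a: Iterable[str],
    set_b: Iterable[str],
    mode: CountMode = "all",
    name_a: str = "A",
    name_b: str = "B",
) -> int:
    """Crosstalk statistic for one pathway pair under the given mode."""
    _check_mode(mode)
    if name_a == name_b:
        raise ValueError(f"cannot count crosstalk of pathway {name_a!r} with itself")
    A, B = set(set_a), set(set_b)
    if mode == "shared_only":
        return len(A & B)
    if mode == "no_shared":
        A, B = A - B, B - A
    count = 0
    # every crossing edge has >=1 endpoint in A, so scanning one side's
    # incident edges suffices; scan the smaller side for speed
    small, other = (A, B) if len(A) <= len(B) else (B, A)
    seen: set[frozenset[str]] = set()
    for u in small:
        if u not in ppi:
            continue
        for v in ppi.graph.neighbors(u):
            if v == u:
                continue
            if v in other or (v in small and u in other):
                e = frozenset((u, v))
                if e not in seen:
                    seen.add(e)
                    count += 1
    return count


def count_all_pairs(
    ppi: PPINetwork,
    coll: PathwayCollection,
    mode: CountMode = "all",
) -> dict[Pair, int]:
    """Crosstalk counts for every unordered pathway pair.

    One pass over the PPI edge list using a gene -> pathways membership
    index; equivalent to calling :func:`count_pair` per pair but much
    faster when many pairs are needed.
    """
    _check_mode(mode)
    membership: dict[str, set[str]] = {}
    for name in coll:
        for g in coll[name]:
            membership.setdefault(g, set()).add(name)
    names = coll.names
    counts = {tuple(sorted(p)): 0 for p in itertools.combinations(names, 2)}
    _accumulate_counts(ppi.edge_list(), membership, mode, counts)
    return counts


def _accumulate_counts(
    edges: Sequence[tuple[str, str]],
    membership: dict[str, set[str]],
    mode: str,
    counts: dict[Pair, int],
) -> None:
    if mode == "shared_only":
        for pws in membership.values():
            if len(pws) > 1:
                for pair in itertools.combinations(sorted(pws), 2):
                    counts[pair] += 1
        return
    no_shared = mode == "no_shared"
    for u, v in edges:
        pu = membership.get(u)
        pv = membership.get(v)
        if not pu or not pv:
            continue
        pairs: set[Pair] = set()
        for P in pu:
            for Q in pv:
                if P == Q:
                    continue
                if no_shared and (Q in pu or P in pv):
                    continue
                pairs.add((P, Q) if P < Q else (Q, P))
        for pr in pairs:
            counts[pr] += 1


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

class _Assignment:
    """Mutable pathway-membership state supporting O(1) random swaps."""

    def __init__(self, coll: PathwayCollection, ppi: PPINetwork) -> None:
        self.names: list[str] = coll.names
        self.lists: list[list[str]] = [sorted(coll[n]) for n in self.names]
        self.pos: list[dict[str, int]] = [
            {g: i for i, g in enumerate(lst)} for lst in self.lists
        ]
        # membership sets keyed by pathway index
        self.membership: dict[str, set[int]] = {}
        for pi, lst in enumerate(self.lists):
            for g in lst:
                self.membership.setdefault(g, set()).add(pi)
        self.degree: dict[str, int] = {}
        for g in self.membership:
            self.degree[g] = ppi.degree(g)

    def swap(self, pi: int, xi: int, qi: int, yi: int) -> None:
        """Exchange gene at position xi of pathway pi with gene yi of qi."""
        x = self.lists[pi][xi]
        y = self.lists[qi][yi]
        self.lists[pi][xi] = y
        self.lists[qi][yi] = x
        ppos, qpos = self.pos[pi], self.pos[qi]
        del ppos[x]
        ppos[y] = xi
        del qpos[y]
        qpos[x] = yi
        mx, my = self.membership[x], self.membership[y]
        mx.discard(pi)
        mx.add(qi)
        my.discard(qi)
        my.add(pi)

    def to_collection(self) -> PathwayCollection:
        return PathwayCollection(
            {n: frozenset(lst) for n, lst in zip(self.names, self.lists)}
        )


def _degree_bin(degree: int) -> int:
    return int(math.floor(math.log2(degree)))


def _apply_swaps(
    state: _Assignment,
    n_swaps: int,
    scheme: str,
    rng: np.random.Generator,
    proposal_cap_factor: int = 1000,
) -> None:
    """Apply exactly ``n_swaps`` accepted gene exchanges in place."""
    K = len(state.lists)
    if K < 2:
        raise ValueError("permutation needs at least two pathways")
    n_swappable = sum(
        any(state.degree[g] >= 1 for g in lst) for lst in state.lists
    )
    if n_swappable < 2:
        raise SwapInfeasibleError(
            f"only {n_swappable} pathway(s) contain a gene with a PPI partner; "
            "a gene exchange needs two"
        )
    if scheme not in {"uniform", "degree_matched"}:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    degree_matched = scheme == "degree_matched"
    sizes = [len(lst) for lst in state.lists]
    cap = max(proposal_cap_factor * max(n_swaps, 1), 1000)
    accepted = 0
    proposals = 0
    last_reason = "no proposal made"
    BATCH = 4096
    while accepted < n_swaps:
        # batched uniform draws: pathway pair + one position in each
        u = rng.random((BATCH, 4))
        for row in u:
            if accepted >= n_swaps:
                break
            proposals += 1
            if proposals > cap:
                raise SwapInfeasibleError(
                    f"gave up after {cap} swap proposals "
                    f"({accepted}/{n_swaps} accepted); last rejection: {last_reason}"
                )
            pi = int(row[0] * K)
            qi = int(row[1] * (K - 1))
            if qi >= pi:
                qi += 1
            xi = int(row[2] * sizes[pi])
            yi = int(row[3] * sizes[qi])
            x = state.lists[pi][xi]
            y = state.lists[qi][yi]
            if x == y:
                last_reason = "proposed genes identical"
                continue
            dx = state.degree[x]
            dy = state.degree[y]
            if dx < 1 or dy < 1:
                last_reason = "proposed gene has no PPI partner"
                continue
            if qi in state.membership[x] or pi in state.membership[y]:
                last_reason = "gene already belongs to the receiving pathway"
                continue
            if degree_matched and _degree_bin(dx) != _degree_bin(dy):
                last_reason = "degree bins differ under degree_matched scheme"
                continue
            state.swap(pi, xi, qi, yi)
            accepted += 1


def permute_collection(
    coll: PathwayCollection,
    ppi: PPINetwork,
    n_swaps: int,
    scheme: str = "uniform",
    rng: np.random.Generator | None = None,
) -> PathwayCollection:
    """Return a new collection after ``n_swaps`` accepted gene exchanges.

    Each accepted exchange moves gene x from pathway P to Q and gene y from
    Q to P, with x != y, both genes having at least one PPI partner, and
    x not already in Q nor y in P (so every pathway size and the global
    membership multiset are conserved exactly).  Under
    ``scheme="degree_matched"`` the two genes must additionally fall in the
    same log2 degree bin.  The input collection is never modified.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(coll) < 2:
        raise ValueError("permutation needs at least two pathways")
    state = _Assignment(coll, ppi)
    if n_swaps > 0:
        _apply_swaps(state, n_swaps, scheme, rng)
    return state.to_collection()


def empirical_p(
    observed: int,
    null_counts: Sequence[int],
    add_one: bool = False,
) -> float:
    """Fraction of null counts >= the observed count.

    With ``add_one`` the (k+1)/(R+1) convention is used instead, which
    never returns exactly zero.
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("empirical p-value needs a non-empty null sample")
    k = int((null_counts >= observed).sum())
    if add_one:
        return (k + 1) / (null_counts.size + 1)
    return k / null_counts.size


def null_distribution(
    coll: PathwayCollection,
    ppi: PPINetwork,
    R: int = 1000,
    n_swaps: int = 100_000,
    mode: CountMode = "all",
    scheme: str = "uniform",
    seed: int | np.random.SeedSequence | None = None,
) -> "CrosstalkResults":
    """Observed counts plus R permutation null counts for every pair.

    Each repetition restarts from the original assignment and uses its own
    deterministic child RNG stream, so the R nulls are exchangeable and the
    whole table is reproducible from ``seed`` alone.
    """
    model = PathwayCrosstalkModel(ppi, coll, mode=mode)
    return model.fit(permutations=R, swaps=n_swaps, scheme=scheme, seed=seed)


def build_pathway_network(
    table: "CrosstalkResults",
    alpha: float = 0.05,
    keep_isolated: bool = False,
) -> PathwayNetwork:
    """Assemble the pathway network from pairs with p_emp strictly below alpha."""
    return table.network(alpha=alpha, keep_isolated=keep_isolated)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PathwayCrosstalkModel:
    """Permutation model for pairwise pathway crosstalk.

    Parameters
    ----------
    ppi
        The interaction universe.  Only edges among pathway-member genes can
        ever contribute to a count, so the edge list is restricted to the
        pathway universe up front.
    pathways
        Named gene sets; overlaps allowed.
    mode
        Counting mode, see module docstring.
    """

    def __init__(
        self,
        ppi: PPINetwork,
        pathways: PathwayCollection,
        mode: CountMode = "all",
    ) -> None:
        _check_mode(mode)
        if len(pathways) < 2:
            raise ValueError("crosstalk needs at least two pathways")
        self.ppi = ppi
        self.pathways = pathways
        self.mode: CountMode = mode
        universe = pathways.universe
        self._edges = [
            (u, v) for u, v in ppi.edge_list() if u in universe and v in universe
        ]
        self._pairs = [
            tuple(sorted(p)) for p in itertools.combinations(pathways.names, 2)
        ]

    @property
    def pairs(self) -> list[Pair]:
        return list(self._pairs)

    def observed_counts(self) -> dict[Pair, int]:
        counts = {p: 0 for p in self._pairs}
        membership: dict[str, set[str]] = {}
        for name in self.pathways:
            for g in self.pathways[name]:
                membership.setdefault(g, set()).add(name)
        _accumulate_counts(self._edges, membership, self.mode, counts)
        return counts

    def fit(
        self,
        permutations: int = 1000,
        swaps: int = 100_000,
        scheme: str = "uniform",
        seed: int | np.random.SeedSequence | None = None,
        alpha: float = 0.05,
        add_one: bool = False,
    ) -> "CrosstalkResults":
        """Run the permutation null and return a results object.

        ``permutations`` (R) independent rewired collections are generated,
        each from the original assignment with ``swaps`` accepted exchanges,
        and the per-pair counts recorded.
        """
        if permutations < 1:
            raise ValueError("need at least one permutation")
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        children = ss.spawn(permutations)
        observed = self.observed_counts()

        name_of = self.pathways.names
        null = np.empty((permutations, len(self._pairs)), dtype=np.int64)
        pair_index = {p: k for k, p in enumerate(self._pairs)}
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            state = _Assignment(self.pathways, self.ppi)
            if swaps > 0:
                _apply_swaps(state, swaps, scheme, rng)
            counts = {p: 0 for p in self._pairs}
            membership_named: dict[str, set[str]] = {
                g: {name_of[i] for i in idxs} for g, idxs in state.membership.items()
            }
            _accumulate_counts(self._edges, membership_named, self.mode, counts)
            for p, c in counts.items():
                null[r, pair_index[p]] = c
        pvals = {
            p: empirical_p(observed[p], null[:, k], add_one=add_one)
            for p, k in pair_index.items()
        }
        return CrosstalkResults(
            model=self,
            observed=observed,
            null_counts={p: null[:, k].copy() for p, k in pair_index.items()},
            p_emp=pvals,
            R=permutations,
            n_swaps=swaps,
            scheme=scheme,
            seed=seed if not isinstance(seed, np.random.SeedSequence) else None,
            alpha=alpha,
        )


@dataclass
class CrosstalkResults:
    """Crosstalk table: observed counts, permutation nulls and empirical p.

    Produced by :meth:`PathwayCrosstalkModel.fit`; also usable directly as
    the per-pair table (``.to_frame()``) or as the source of the significant
    pathway network (``.network()``).
    """

    model: PathwayCrosstalkModel
    observed: dict[Pair, int]
    null_counts: dict[Pair, np.ndarray]
    p_emp: dict[Pair, float]
    R: int
    n_swaps: int
    scheme: str
    seed: int | None
    alpha: float = 0.05

    @property
    def mode(self) -> str:
        return self.model.mode

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway_a": a,
                "pathway_b": b,
                "observed": self.observed[(a, b)],
                "null_mean": float(np.mean(self.null_counts[(a, b)])),
                "p_emp": self.p_emp[(a, b)],
                "significant": self.p_emp[(a, b)] < self.alpha,
            }
            for a, b in sorted(self.observed)
        ]
        return pd.DataFrame(rows)

    def pvalues_adjusted(self, method: str = "fdr_bh") -> dict[Pair, float]:
        """Optional multiple-testing adjustment over the pair tests."""
        from statsmodels.stats.multitest import multipletests

        pairs = sorted(self.p_emp)
        _, adj, _, _ = multipletests([self.p_emp[p] for p in pairs], method=method)
        return dict(zip(pairs, adj))

    def network(
        self, alpha: float | None = None, keep_isolated: bool = False
    ) -> PathwayNetwork:
        """Pathway network of pairs with p_emp strictly below alpha."""
        a = self.alpha if alpha is None else alpha
        net = PathwayNetwork(alpha=a)
        for pair in sorted(self.observed):
            p = self.p_emp[pair]
            if p < a:
                net.add_edge(pair[0], pair[1], count=self.observed[pair],
                             p_value=p, significant=True)
        if keep_isolated:
            for name in self.model.pathways:
                net.add_node(name)
        return net

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-flavoured)."""
        net = self.network()
        s = net.summary()
        df = self.to_frame()
        lines = [
            "Pathway crosstalk permutation results",
            "=" * 54,
            f"pathways:        {len(self.model.pathways)}",
            f"pairs tested:    {len(self.observed)}",
            f"counting mode:   {self.mode}",
            f"permutations R:  {self.R}   swaps/permutation: {self.n_swaps}",
            f"scheme:          {self.scheme}   seed: {self.seed}",
            f"significant (p < {self.alpha:g}): {int(df['significant'].sum())} pairs",
            f"network: {s.n_nodes} nodes, {s.n_edges} edges, "
            f"average degree {s.average_degree}",
            "=" * 54,
        ]
        top = df.sort_values(["p_emp", "pathway_a", "pathway_b"]).head(10)
        lines.append(top.to_string(index=False))
        return "\n".join(lines)
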