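import itertools
import math

import numpy as np
import pytest

from cspnet import (
    PathwayCollection,
    PPINetwork,
    PathwayCrosstalkModel,
    SwapInfeasibleError,
    build_pathway_network,
    count_all_pairs,
    count_pair,
    empirical_p,
    network_summary,
    null_distribution,
    permute_collection,
)
from conftest import random_ppi


def brute_count(edge_set, A, B, mode):
    """Exhaustive reference counter over an explicit undirected edge list."""
    if mode == "shared_only":
        return len(A & B)
    n = 0
    for u, v in edge_set:
        if u == v:
            continue
        if mode == "all":
            n += (u in A and v in B) or (u in B and v in A)
        else:
            n += (u in A - B and v in B - A) or (u in B - A and v in A - B)
    return n


def random_instance(rng, max_genes=10, max_pathways=3):
    n = int(rng.integers(3, max_genes + 1))
    genes = [f"g{i}" for i in range(n)]
    pairs = list(itertools.combinations(genes, 2))
    keep = rng.random(len(pairs)) < 0.4
    edges = [p for p, k in zip(pairs, keep) if k]
    if not edges:
        edges = [tuple(genes[:2])]
    k = int(rng.integers(2, max_pathways + 1))
    sets = {}
    for i in range(k):
        size = int(rng.integers(1, n + 1))
        sets[f"P{i}"] = set(rng.choice(genes, size=size, replace=False))
    return PPINetwork(edges), edges, sets


class TestCountPair:
    def test_shared_gene_instance_all_modes(self, shared_gene_instance):
        ppi, A, B = shared_gene_instance
        # the shared gene g2 acts on both sides; the share itself never counts
        assert count_pair(ppi, A, B, "all") == 2
        assert count_pair(ppi, A, B, "no_shared") == 0
        assert count_pair(ppi, A, B, "shared_only") == 1

    def test_self_loops_never_counted(self):
        ppi = PPINetwork([("g1", "g1"), ("g1", "g2")])
        assert count_pair(ppi, {"g1"}, {"g2"}, "all") == 1
        assert count_pair(ppi, {"g1", "g2"}, {"g1", "g2"}, "all", "A", "B") == 1

    def test_identical_names_rejected(self, tiny_ppi):
        with pytest.raises(ValueError):
            count_pair(tiny_ppi, {"g1"}, {"g2"}, name_a="P", name_b="P")

    @pytest.mark.parametrize("mode", ["all", "no_shared", "shared_only"])
    def test_symmetry_and_mode_ordering(self, rng, mode):
        for _ in range(50):
            ppi, edges, sets = random_instance(rng)
            names = list(sets)
            A, B = sets[names[0]], sets[names[1]]
            assert count_pair(ppi, A, B, mode) == count_pair(ppi, B, A, mode)
            assert count_pair(ppi, A, B, "all") >= count_pair(ppi, A, B, "no_shared")

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            ppi, edges, sets = random_instance(rng)
            for (na, A), (nb, B) in itertools.combinations(sets.items(), 2):
                for mode in ("all", "no_shared", "shared_only"):
                    assert count_pair(ppi, A, B, mode) == brute_count(edges, A, B, mode)

    def test_count_all_pairs_agrees_with_count_pair(self, rng):
        for _ in range(30):
            ppi, edges, sets = random_instance(rng, max_genes=12, max_pathways=3)
            coll = PathwayCollection({k: v for k, v in sets.items() if v})
            for mode in ("all", "no_shared", "shared_only"):
                table = count_all_pairs(ppi, coll, mode)
                for (a, b), c in table.items():
                    assert c == count_pair(ppi, coll[a], coll[b], mode)


def membership_multiset(coll):
    out = {}
    for name in coll:
        for g in coll[name]:
            out[g] = out.get(g, 0) + 1
    return out


class TestPermutation:
    def _setup(self, rng, n_genes=30, n_pathways=4, size=6):
        ppi = random_ppi(rng, n_genes, 0.2)
        genes = [f"g{i}" for i in range(n_genes)]
        perm = rng.permutation(n_genes)
        coll = PathwayCollection({
            f"P{k}": {genes[i] for i in perm[k * size:(k + 1) * size]}
            for k in range(n_pathways)
        })
        return ppi, coll

    def test_sizes_and_multiset_conserved(self, rng):
        ppi, coll = self._setup(rng)
        out = permute_collection(coll, ppi, 200, rng=rng)
        assert {n: len(out[n]) for n in out} == {n: len(coll[n]) for n in coll}
        assert membership_multiset(out) == membership_multiset(coll)

    def test_input_collection_untouched(self, rng):
        ppi, coll = self._setup(rng)
        before = {n: set(coll[n]) for n in coll}
        permute_collection(coll, ppi, 100, rng=rng)
        assert {n: set(coll[n]) for n in coll} == before

    def test_zero_swaps_is_identity(self, rng):
        ppi, coll = self._setup(rng)
        assert permute_collection(coll, ppi, 0, rng=rng) == coll

    def test_only_connected_genes_move(self, rng):
        ppi, coll = self._setup(rng, n_genes=40)
        out = permute_collection(coll, ppi, 150, rng=rng)
        for name in coll:
            for g in coll[name] ^ out[name]:
                assert ppi.degree(g) >= 1

    def test_degree_matched_moves_within_bins(self, rng):
        ppi, coll = self._setup(rng, n_genes=40)
        out = permute_collection(coll, ppi, 100, scheme="degree_matched", rng=rng)
        # every gene that changed pathways must have a same-bin counterpart
        # moving the other way; check the bin multiset per pathway is invariant
        def bins(genes):
            out = {}
            for g in genes:
                b = int(math.floor(math.log2(ppi.degree(g))))
                out[b] = out.get(b, 0) + 1
            return out

        for name in coll:
            assert bins(coll[name]) == bins(out[name])

    def test_infeasible_when_too_few_connected_pathways(self):
        ppi = PPINetwork([("g1", "g2")])
        coll = PathwayCollection({"A": {"g1", "g2"}, "B": {"x1", "x2"}})
        with pytest.raises(SwapInfeasibleError, match="pathway"):
            permute_collection(coll, ppi, 5, rng=np.random.default_rng(0))

    def test_null_mean_matches_exhaustive_enumeration(self):
        # 6 genes on a cycle (all degree 2), two pathways of 3: the null over
        # all C(6,3) = 20 assignments is enumerable exactly
        genes = [f"g{i}" for i in range(6)]
        edges = [(genes[i], genes[(i + 1) % 6]) for i in range(6)]
        ppi = PPINetwork(edges)
        coll = PathwayCollection({"A": set(genes[:3]), "B": set(genes[3:])})
        exact = []
        for combo in itertools.combinations(genes, 3):
            A = set(combo)
            B = set(genes) - A
            exact.append(brute_count(edges, A, B, "all"))
        exact_mean = np.mean(exact)
        res = null_distribution(coll, ppi, R=600, n_swaps=40, mode="all", seed=5)
        null = res.null_counts[("A", "B")]
        se = null.std(ddof=1) / math.sqrt(len(null))
        assert abs(null.mean() - exact_mean) < 3 * se

    def test_uniform_and_degree_matched_agree_on_homogeneous_graph(self, rng):
        # near-regular background: the two schemes should give approximately
        # the same per-pair null counts
        ppi, coll = self._setup(np.random.default_rng(11), n_genes=60, size=12)
        a = null_distribution(coll, ppi, R=80, n_swaps=400, scheme="uniform", seed=1)
        b = null_distribution(coll, ppi, R=80, n_swaps=400, scheme="degree_matched", seed=2)
        for pair in a.null_counts:
            ma, mb = a.null_counts[pair].mean(), b.null_counts[pair].mean()
            assert abs(ma - mb) / max(ma, mb) < 0.10


class TestEmpiricalP:
    def test_observed_zero_gives_one(self, rng):
        null = rng.integers(0, 50, size=1000)
        assert empirical_p(0, null) == 1.0

    def test_observed_above_null_max_gives_zero(self):
        assert empirical_p(5, [0, 1, 2, 3, 4] * 200) == 0.0

    def test_constructed_five_percent(self):
        null = [3] * 50 + [0] * 950
        assert empirical_p(3, null) == 0.05

    def test_non_increasing_in_observed(self, rng):
        null = rng.integers(0, 30, size=500)
        ps = [empirical_p(o, null) for o in range(0, 35)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_add_one_variant_never_zero(self):
        assert empirical_p(99, [0] * 999, add_one=True) == pytest.approx(1 / 1000)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1, [])


class TestFitAndNetwork:
    def _fit(self, seed=3, **kwargs):
        rng = np.random.default_rng(2)
        ppi = random_ppi(rng, 40, 0.15)
        genes = [f"g{i}" for i in range(40)]
        perm = rng.permutation(40)
        coll = PathwayCollection({
            f"P{k}": {genes[i] for i in perm[k * 10:(k + 1) * 10]} for k in range(3)
        })
        model = PathwayCrosstalkModel(ppi, coll)
        return model.fit(permutations=kwargs.pop("permutations", 10),
                         swaps=kwargs.pop("swaps", 50), seed=seed, **kwargs)

    def test_each_pair_has_R_null_counts(self):
        res = self._fit(permutations=10)
        assert len(res.null_counts) == 3
        assert all(len(v) == 10 for v in res.null_counts.values())

    def test_fixed_seed_reproducible(self):
        a, b = self._fit(seed=9), self._fit(seed=9)
        assert a.observed == b.observed
        assert all((a.null_counts[p] == b.null_counts[p]).all() for p in a.null_counts)

    def test_p_consistent_with_null_counts(self):
        res = self._fit(permutations=20)
        for pair, null in res.null_counts.items():
            assert res.p_emp[pair] == (null >= res.observed[pair]).mean()

    def test_strict_alpha_threshold(self):
        res = self._fit()
        res.p_emp = {p: v for p, v in zip(res.p_emp, (0.049, 0.05, 0.2))}
        net = build_pathway_network(res, alpha=0.05)
        assert net.n_edges == 1

    def test_alpha_above_one_keeps_all_pairs(self):
        res = self._fit()
        assert build_pathway_network(res, alpha=1.1).n_edges == 3

    def test_empty_network_is_valid(self):
        res = self._fit()
        res.p_emp = {p: 1.0 for p in res.p_emp}
        net = build_pathway_network(res, alpha=0.05)
        assert net.n_nodes == 0 and network_summary(net).average_degree == 0.0

    def test_keep_isolated_includes_all_pathways(self):
        res = self._fit()
        res.p_emp = {p: 1.0 for p in res.p_emp}
        assert build_pathway_network(res, alpha=0.05, keep_isolated=True).n_nodes == 3

    def test_summary_and_frame(self):
        res = self._fit()
        df = res.to_frame()
        assert list(df.columns) == [
            "pathway_a", "pathway_b", "observed", "null_mean", "p_emp", "significant"
        ]
        assert "permutations R" in res.summary()
        adj = res.pvalues_adjusted()
        assert all(adj[p] >= res.p_emp[p] - 1e-12 for p in adj)


class TestNetworkSummary:
    def test_empty_network(self):
        from cspnet import PathwayNetwork

        net = PathwayNetwork()
        for _ in range(10):
            pass
        net.add_node("X")
        s = network_summary(net)
        assert (s.n_nodes, s.n_edges, s.average_degree) == (1, 0, 0.0)

    def test_edges_per_node_convention(self):
        from cspnet import PathwayNetwork

        net = PathwayNetwork()
        net.add_edge("A", "B", count=1, p_value=0.01)
        net.add_edge("B", "C", count=1, p_value=0.01)
        net.add_edge("C", "A", count=1, p_value=0.01)
        s = network_summary(net)
        assert s.average_degree == 1.0       # 3 edges / 3 nodes
        assert s.mean_degree == pytest.approx(2.0)
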