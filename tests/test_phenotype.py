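import dataclasses

import numpy as np
import pandas as pd
import pytest

from cspnet import (
    PathwayCollection,
    PPINetwork,
    PhenotypeSeriesModel,
    SynthConfig,
    PlantedPair,
    active_ppis,
    call_de_genes,
    generate_dataset,
    phenotype_network_series,
)
from cspnet.io import ExpressionMatrix


def expr_matrix(rows, tps=("0h", "1h"), baseline="0h", condition="c"):
    df = pd.DataFrame(rows, columns=list(tps), dtype=float)
    df.index = [f"g{i + 1}" for i in range(len(rows))]
    return ExpressionMatrix(values=df, baseline=baseline, condition=condition)


class TestDECalls:
    def test_bidirectional_fold_change(self):
        # up 10->25 (ratio 2.36 with pseudocount), flat 10->15, down 10->4
        m = expr_matrix([[10, 25], [10, 15], [10, 4]])
        de = call_de_genes(m, "1h", fc_threshold=2.0)
        assert de.de_genes == {"g1", "g3"}
        assert de.condition == "c" and de.timepoint == "1h"

    def test_pseudocount_stabilises_zero_baseline(self):
        m = expr_matrix([[0, 0.5]])
        de = call_de_genes(m, "1h", fc_threshold=2.0, pseudocount=1.0)
        assert de.de_genes == set()   # (0.5+1)/(0+1) = 1.5 < 2

    def test_baseline_and_unknown_timepoint_rejected(self):
        m = expr_matrix([[1, 2]])
        with pytest.raises(ValueError):
            call_de_genes(m, "0h")
        with pytest.raises(ValueError):
            call_de_genes(m, "99h")
        with pytest.raises(ValueError):
            call_de_genes(m, "1h", fc_threshold=1.0)

    def test_raising_threshold_never_enlarges_de_set(self, rng):
        vals = rng.uniform(1, 200, size=(50, 2))
        m = expr_matrix(vals.tolist())
        prev = None
        for fc in (1.5, 2.0, 3.0, 5.0):
            de = call_de_genes(m, "1h", fc_threshold=fc).de_genes
            if prev is not None:
                assert de <= prev
            prev = de

    def test_relevant_genes_are_de_plus_neighbours(self, tiny_ppi):
        m = expr_matrix([[10, 30], [10, 10], [10, 10]])  # g1 DE
        de = call_de_genes(m, "1h", ppi=tiny_ppi)
        assert de.de_genes == {"g1"}
        assert de.relevant_genes == {"g1", "g2"}


class TestActivePPIs:
    def test_edges_with_one_de_endpoint(self):
        ppi = PPINetwork([("g1", "g2"), ("g3", "g4")])
        m = expr_matrix([[10, 30], [10, 10], [10, 10], [10, 10]])
        de = call_de_genes(m, "1h")
        act = active_ppis(ppi, de)
        assert act.edges == frozenset({frozenset({"g1", "g2"})})

    def test_no_de_genes_no_active_edges(self):
        ppi = PPINetwork([("g1", "g2")])
        m = expr_matrix([[10, 10], [10, 10]])
        act = active_ppis(ppi, call_de_genes(m, "1h"))
        assert act.edges == frozenset()

    def test_all_de_gives_all_edges(self):
        ppi = PPINetwork([("g1", "g2"), ("g2", "g3")])
        m = expr_matrix([[10, 30], [10, 30], [10, 30]])
        act = active_ppis(ppi, call_de_genes(m, "1h"))
        assert act.edges == ppi.edge_set()

    def test_monotone_in_de_set(self, rng):
        from conftest import random_ppi
        from cspnet.phenotype import DECall

        ppi = random_ppi(rng, 30, 0.1)
        genes = sorted(ppi.genes)
        small = set(genes[:5])
        big = set(genes[:12])
        mk = lambda s: DECall("c", "t", frozenset(s), 2.0, frozenset(s))
        assert active_ppis(ppi, mk(small)).edges <= active_ppis(ppi, mk(big)).edges


def small_dataset(noise=0.0, seed=11):
    cfg = SynthConfig(
        n_genes=260,
        edge_density=0.01,
        n_pathways=6,
        size_range=(15, 20),
        overlap_fraction=0.1,
        planted_pairs=(
            PlantedPair("P01", "P02", n_cross_edges=25),
            PlantedPair("P04", "P05", n_cross_edges=25, schedule=("t2", "t4")),
        ),
        conditions=("c1",),
        noise_sd=noise,
    )
    return generate_dataset(cfg, seed=seed)


class TestPhenotypeSeries:
    def _comprehensive(self, ds, seed=5):
        from cspnet import PathwayCrosstalkModel

        return PathwayCrosstalkModel(ds.ppi, ds.pathways).fit(
            permutations=150, swaps=500, seed=seed
        ).network()

    def test_persistent_pair_present_at_all_timepoints(self):
        ds = small_dataset()
        comp = self._comprehensive(ds)
        res = phenotype_network_series(
            ds.expression["c1"], ds.ppi, ds.pathways, comprehensive=comp,
            permutations=120, swaps=400, seed=21,
        )
        assert all(res.networks[t].has_edge("P01", "P02") for t in res.timepoints)
        pres = res.presence()[("P04", "P05")]
        assert pres == [t in ("t2", "t4") for t in res.timepoints]

    def test_backbone_restriction_subsets_comprehensive(self):
        ds = small_dataset()
        comp = self._comprehensive(ds)
        res = phenotype_network_series(
            ds.expression["c1"], ds.ppi, ds.pathways, comprehensive=comp,
            permutations=80, swaps=300, seed=22,
        )
        for t in res.timepoints:
            assert res.networks[t].edge_set() <= comp.edge_set()

    def test_flat_series_gives_empty_networks(self):
        ds = small_dataset()
        expr = ds.expression["c1"]
        flat = ExpressionMatrix(
            values=pd.DataFrame(
                100.0, index=expr.values.index, columns=expr.values.columns
            ),
            baseline=expr.baseline,
            condition="flat",
        )
        res = phenotype_network_series(
            flat, ds.ppi, ds.pathways, restriction="none",
            permutations=20, swaps=50, seed=1,
        )
        assert all(res.networks[t].n_edges == 0 for t in res.timepoints)

    def test_support_filter_keeps_supported_backbone_edges(self):
        ds = small_dataset()
        comp = self._comprehensive(ds)
        model = PhenotypeSeriesModel(
            ds.expression["c1"], ds.ppi, ds.pathways, comprehensive=comp,
            restriction="none", support_filter=True,
        )
        res = model.fit(seed=3)
        for t in res.timepoints:
            net = res.networks[t]
            assert net.edge_set() <= comp.edge_set()
        # persistent supporters are active at every timepoint
        assert all(res.networks[t].has_edge("P01", "P02") for t in res.timepoints)

    def test_enriched_only_restriction_drops_unenriched_pathways(self):
        ds = small_dataset()
        model = PhenotypeSeriesModel(
            ds.expression["c1"], ds.ppi, ds.pathways, restriction="enriched_only",
        )
        res = model.fit(permutations=60, swaps=200, seed=4)
        from cspnet import enrich_pathways

        universe = ds.pathways.universe | ds.ppi.genes
        for t in res.timepoints:
            query = set(res.de_calls[t].relevant_genes) & universe
            enriched = {
                r.pathway
                for r in enrich_pathways(ds.pathways, query, universe)
                if r.enriched
            }
            assert res.networks[t].nodes <= enriched

    def test_restriction_requires_comprehensive(self):
        ds = small_dataset()
        with pytest.raises(ValueError, match="comprehensive"):
            PhenotypeSeriesModel(ds.expression["c1"], ds.ppi, ds.pathways)

    def test_summary_mentions_all_timepoints(self):
        ds = small_dataset()
        res = phenotype_network_series(
            ds.expression["c1"], ds.ppi, ds.pathways, restriction="none",
            permutations=20, swaps=50, seed=2,
        )
        s = res.summary()
        assert all(t in s for t in res.timepoints)
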