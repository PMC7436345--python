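import math

import numpy as np
import pytest

from netpharm import (SimConfig, filter_adme, gen_background_ppi, gen_bundle,
                      gen_compound_catalog, gen_expression, gen_gene_sets,
                      gen_target_map, gene_universe)
from netpharm.errors import ConfigError


class TestCatalogGenerator:
    def test_exact_pass_count_planted(self):
        cfg = SimConfig(seed=11, adme_pass_fraction=0.67,
                        n_compounds_per_herb={"A": 40, "B": 30, "C": 30})
        recs = gen_compound_catalog(cfg)
        assert len(recs) == 100
        assert len(filter_adme(recs)) == math.ceil(0.67 * 100) == 67

    @pytest.mark.parametrize("fraction,expected", [(1.0, 50), (0.0, 0)])
    def test_extreme_fractions(self, fraction, expected):
        cfg = SimConfig(seed=2, adme_pass_fraction=fraction,
                        n_compounds_per_herb={"A": 50})
        assert len(filter_adme(gen_compound_catalog(cfg))) == expected

    def test_deterministic(self):
        a = gen_compound_catalog(SimConfig(seed=5))
        b = gen_compound_catalog(SimConfig(seed=5))
        assert a == b


class TestTargetMapGenerator:
    def test_union_bookkeeping_and_determinism(self):
        cfg = SimConfig(seed=1)
        compounds = gen_compound_catalog(cfg)
        tm1, truth1 = gen_target_map(cfg, compounds)
        tm2, truth2 = gen_target_map(cfg, compounds)
        assert tm1.edges == tm2.edges and truth1 == truth2
        assert {g for _, g in tm1.edges} == set(truth1["union"])

    def test_empty_compounds_give_empty_map(self):
        tm, truth = gen_target_map(SimConfig(seed=1), [])
        assert tm.edges == set() and truth["union"] == []

    def test_must_include_genes_are_covered(self):
        cfg = SimConfig(seed=3)
        compounds = gen_compound_catalog(cfg)
        wanted = {"G00001", "G00002", "G00003"}
        tm, truth = gen_target_map(cfg, compounds, must_include=wanted)
        assert wanted <= set(truth["union"])


class TestExpressionGenerator:
    def test_no_planted_effects_means_empty_truth(self):
        _, truth = gen_expression(SimConfig(seed=1, n_genes=50, n_deg_planted=0))
        assert truth["all"] == []

    def test_planted_log2fc_near_delta(self):
        cfg = SimConfig(seed=8, n_genes=500, n_deg_planted=50)
        m, truth = gen_expression(cfg)
        case = m.group_columns("case")
        ctrl = m.group_columns("control")
        lfc = case.mean(axis=1) - ctrl.mean(axis=1)
        bound = 3 * cfg.noise_sd * math.sqrt(2 / cfg.n_per_group)
        idx = {g: i for i, g in enumerate(m.genes)}
        for gene in truth["up"]:
            assert abs(lfc[idx[gene]] - cfg.effect_delta) < bound
        for gene in truth["down"]:
            assert abs(lfc[idx[gene]] + cfg.effect_delta) < bound

    def test_bit_identical_reproduction(self):
        m1, t1 = gen_expression(SimConfig(seed=9, n_genes=100, n_deg_planted=20))
        m2, t2 = gen_expression(SimConfig(seed=9, n_genes=100, n_deg_planted=20))
        assert np.array_equal(m1.values, m2.values) and t1 == t2

    def test_group_sizes(self):
        m, _ = gen_expression(SimConfig(seed=0, n_genes=20, n_deg_planted=4))
        assert m.group_columns("case").shape[1] == 12
        assert m.group_columns("control").shape[1] == 12


class TestPpiGenerator:
    def test_simple_graph_no_self_loops(self):
        edges, truth = gen_background_ppi(SimConfig(seed=4))
        assert all(u != v for u, v in edges)
        assert len(edges) == len(set(map(frozenset, edges))) == truth["n_edges"]

    def test_heavy_tailed_degrees(self):
        import networkx as nx
        edges, _ = gen_background_ppi(SimConfig(seed=4))
        g = nx.Graph(edges)
        degrees = sorted(d for _, d in g.degree())
        assert degrees[-1] > 5 * degrees[len(degrees) // 2]

    def test_edge_bookkeeping(self):
        cfg = SimConfig(seed=4)
        edges, truth = gen_background_ppi(cfg)
        assert truth["base_edges"] == cfg.ppi_attach_m * (cfg.ppi_n_nodes - cfg.ppi_attach_m)
        assert truth["n_edges"] == truth["base_edges"] + truth["planted_extra_edges"]

    def test_hubs_sit_atop_the_degree_distribution(self):
        import networkx as nx
        edges, truth = gen_background_ppi(SimConfig(seed=4))
        g = nx.Graph(edges)
        degrees = dict(g.degree())
        median = sorted(degrees.values())[len(degrees) // 2]
        # every planted hub dominates the typical node by a wide margin;
        # the occasional organic hub may interleave with the weakest plant
        assert all(degrees[h] >= 8 * median for h in truth["hubs"])
        top13 = {n for n, _ in
                 sorted(degrees.items(), key=lambda kv: -kv[1])[:13]}
        assert set(truth["hubs"]) <= top13

    def test_include_genes_become_nodes(self):
        import networkx as nx
        want = {"G00100", "G00200"}
        edges, _ = gen_background_ppi(SimConfig(seed=4), include_genes=want)
        assert want <= set(nx.Graph(edges).nodes())

    def test_deterministic(self):
        e1, t1 = gen_background_ppi(SimConfig(seed=6))
        e2, t2 = gen_background_ppi(SimConfig(seed=6))
        assert e1 == e2 and t1 == t2


class TestGeneSetGenerator:
    def test_planted_overlap_exact(self):
        cfg = SimConfig(seed=2, planted_term_overlap=10)
        targets = set(gene_universe(cfg)[:30])
        coll, truth = gen_gene_sets(cfg, targets, n_planted=4)
        for tid in truth["planted_terms"]:
            members = coll.terms[tid][2]
            assert len(members & targets) == 10

    def test_collection_invariants(self):
        cfg = SimConfig(seed=2)
        coll, _ = gen_gene_sets(cfg, set(gene_universe(cfg)[:40]))
        for _, (_, _, members) in coll.terms.items():
            assert members and members <= coll.background

    def test_overlap_larger_than_list_rejected(self):
        cfg = SimConfig(seed=2, planted_term_overlap=15)
        with pytest.raises(ConfigError):
            gen_gene_sets(cfg, {"G00001"})

    def test_deterministic(self):
        cfg = SimConfig(seed=2)
        targets = set(gene_universe(cfg)[:40])
        c1, t1 = gen_gene_sets(cfg, targets)
        c2, t2 = gen_gene_sets(cfg, targets)
        assert c1.terms == c2.terms and t1 == t2


class TestBundle:
    def test_planted_common_overlap_is_exact(self, default_bundle):
        truth = default_bundle.truth
        union = set(truth["target_map"]["union"])
        planted_deg = set(truth["deg"]["all"])
        assert union & planted_deg == set(truth["common_targets"])
        assert len(truth["common_targets"]) == default_bundle.config.n_common_planted

    def test_common_genes_in_ppi_background(self, default_bundle):
        import networkx as nx
        nodes = set(nx.Graph(default_bundle.ppi_edges).nodes())
        assert set(default_bundle.truth["common_targets"]) <= nodes

    def test_bundle_files_written(self, bundle_dir):
        for path in bundle_dir.values():
            assert path.exists() and path.stat().st_size > 0

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigError):
            SimConfig(noise_sd=0.0)
        with pytest.raises(ConfigError):
            SimConfig(ppi_attach_m=500, ppi_n_nodes=400)
        with pytest.raises(ConfigError):
            SimConfig(adme_pass_fraction=1.5)
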