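"""Synthetic study generator: planted structure and determinism."""

import networkx as nx
import numpy as np
import pytest

from netprio import synthetic as S


class TestGenerateInteractome:
    @pytest.mark.parametrize(
        "n, m, expected_edges",
        [(100, 2, 196), (3, 1, 2), (1358, 3, 4065)],
    )
    def test_edge_count_formula(self, n, m, expected_edges):
        graph = S.generate_interactome(n, m, seed=1)
        assert graph.number_of_nodes() == n
        assert graph.number_of_edges() == expected_edges == (n - m) * m

    def test_beta_cell_scale_density(self):
        # ~3 edges/node, same order as a dense query network (~2.6)
        graph = S.generate_interactome(1358, 3, seed=42)
        ratio = graph.number_of_edges() / graph.number_of_nodes()
        assert 2.0 < ratio < 3.5

    def test_connected_simple_and_labeled(self):
        graph = S.generate_interactome(200, 2, seed=3)
        assert nx.is_connected(graph)
        assert nx.number_of_selfloops(graph) == 0
        assert sorted(graph)[0] == "G0001"

    def test_deterministic_for_fixed_seed(self):
        g1 = S.generate_interactome(150, 2, seed=9)
        g2 = S.generate_interactome(150, 2, seed=9)
        assert sorted(g1.edges) == sorted(g2.edges)
        g3 = S.generate_interactome(150, 2, seed=10)
        assert sorted(g1.edges) != sorted(g3.edges)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            S.generate_interactome(3, 3, seed=1)
        with pytest.raises(ValueError):
            S.generate_interactome(10, 0, seed=1)


class TestPlantHubs:
    def test_degrees_increase_exactly(self):
        graph = S.generate_interactome(500, 2, seed=3)
        before = dict(graph.degree)
        planted, hubs = S.plant_hubs(graph, 5, extra_degree=40, seed=3)
        assert len(hubs) == 5
        for hub in hubs:
            assert planted.degree(hub) == before[hub] + 40
        assert nx.number_of_selfloops(planted) == 0

    def test_zero_hubs_is_identity(self):
        graph = S.generate_interactome(50, 2, seed=4)
        planted, hubs = S.plant_hubs(graph, 0, extra_degree=10, seed=4)
        assert hubs == set()
        assert sorted(planted.edges) == sorted(graph.edges)

    def test_original_graph_untouched(self):
        graph = S.generate_interactome(50, 2, seed=4)
        edges_before = sorted(graph.edges)
        S.plant_hubs(graph, 2, extra_degree=5, seed=4)
        assert sorted(graph.edges) == edges_before

    def test_impossible_request_rejected(self):
        graph = nx.complete_graph(5)
        with pytest.raises(ValueError):
            S.plant_hubs(graph, 1, extra_degree=4, seed=0)  # no non-neighbors left
        with pytest.raises(ValueError, match="node count"):
            S.plant_hubs(graph, 6, extra_degree=1, seed=0)


class TestGenerateExpression:
    def test_shapes_truth_and_determinism(self):
        config = S.SyntheticStudyConfig(n_genes=200, seed=7)
        symbols = S.gene_symbols(200)
        matrix, truth = S.generate_expression(config, symbols)
        assert matrix.values.shape == (200, 67)
        assert len(truth.true_deg_genes) == 20
        assert set(truth.true_directions) == truth.true_deg_genes
        ups = sum(1 for d in truth.true_directions.values() if d == "up")
        assert ups == 10  # 50/50 split
        matrix2, truth2 = S.generate_expression(config, symbols)
        assert np.array_equal(matrix.values, matrix2.values)
        assert truth2.true_directions == truth.true_directions

    def test_forced_genes_planted(self):
        config = S.SyntheticStudyConfig(n_genes=100, seed=8)
        _, truth = S.generate_expression(config, S.gene_symbols(100),
                                         forced_deg_genes=["G0001", "G0002"])
        assert {"G0001", "G0002"} <= truth.true_deg_genes

    def test_no_missing_values(self):
        config = S.SyntheticStudyConfig(n_genes=50, seed=9)
        matrix, _ = S.generate_expression(config, S.gene_symbols(50))
        assert not matrix.values.isna().any().any()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="deg_fraction"):
            S.SyntheticStudyConfig(deg_fraction=1.5)
        with pytest.raises(ValueError, match="per group"):
            S.SyntheticStudyConfig(n_case=1, n_control=5)
        with pytest.raises(ValueError, match="noise_sd"):
            S.SyntheticStudyConfig(noise_sd=0.0)


class TestGenerateDrugTable:
    def test_hub_bias_enriches_high_degree_targets(self):
        """Mean degree of drugged genes exceeds the graph mean (20 replicates)."""
        graph = S.generate_interactome(200, 2, seed=9)
        degree = dict(graph.degree)
        mean_degree = np.mean(list(degree.values()))
        wins = 0
        for rep in range(20):
            records, _ = S.generate_drug_table(graph, 20, hub_bias=2.0, seed=900 + rep)
            drugged = np.mean([degree[r.gene] for r in records])
            wins += drugged > mean_degree
        assert wins == 20

    def test_extreme_bias_targets_star_center(self, star5):
        # weight 4^50 vs 1: the center is all but surely among the targets
        for seed in range(5):
            records, _ = S.generate_drug_table(star5, 1, hub_bias=50.0, seed=seed)
            assert "C" in {r.gene for r in records}

    def test_target_counts_and_groups(self):
        graph = S.generate_interactome(50, 2, seed=2)
        records, truth = S.generate_drug_table(graph, 10, hub_bias=1.0, seed=5)
        per_drug = {}
        for rec in records:
            per_drug.setdefault(rec.drug_name, set()).add(rec.gene)
            assert rec.groups <= {"approved", "experimental", "investigational"}
        assert len(per_drug) == 10
        assert all(1 <= len(ts) <= 4 for ts in per_drug.values())
        assert truth.planted_drug_links == {
            (r.drug_name, r.gene) for r in records
        }

    def test_deterministic(self):
        graph = S.generate_interactome(50, 2, seed=2)
        r1, _ = S.generate_drug_table(graph, 5, hub_bias=1.0, seed=6)
        r2, _ = S.generate_drug_table(graph, 5, hub_bias=1.0, seed=6)
        assert r1 == r2


def test_config_from_mapping_coerces_and_rejects_unknown():
    config = S.config_from_mapping({"n_genes": "500", "deg_fraction": "0.2", "seed": 3})
    assert config.n_genes == 500 and config.deg_fraction == 0.2
    with pytest.raises(ValueError, match="unknown"):
        S.config_from_mapping({"n_genez": 1})


def test_truth_tsv(tmp_path):
    truth = S.SyntheticTruth(
        true_deg_genes={"G1"}, true_directions={"G1": "up"},
        planted_hub_genes={"G2"}, planted_drug_links={("DrugA", "G1")},
    )
    path = tmp_path / "truth.tsv"
    S.write_truth(truth, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "kind\tkey\tvalue"
    assert "deg\tG1\tup" in lines and "hub\tG2\t" in lines
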