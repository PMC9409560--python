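import networkx as nx
import numpy as np
import pytest

from netoverlap import (
    SimulationConfig,
    plant_module,
    plant_overlapping_sets,
    simulate_expression,
    simulate_interactome,
)
from netoverlap.synthetic import write_fixture_bundle


class TestSimulateInteractome:
    def test_complete_er_graph(self):
        g = simulate_interactome(SimulationConfig(seed=1, n_nodes=100, model_params={"p": 1.0}))
        assert g.number_of_edges() == 4950

    def test_barabasi_albert_edge_count(self):
        g = simulate_interactome(
            SimulationConfig(seed=2, n_nodes=500, graph_model="barabasi_albert",
                             model_params={"m": 2})
        )
        assert g.number_of_edges() == (500 - 2) * 2

    def test_duplication_divergence_runs(self):
        g = simulate_interactome(
            SimulationConfig(seed=3, n_nodes=200, graph_model="duplication_divergence",
                             model_params={"p": 0.4})
        )
        assert g.number_of_nodes() == 200

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=4, n_nodes=300, model_params={"p": 0.01})
        g1, g2 = simulate_interactome(cfg), simulate_interactome(cfg)
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))

    def test_gene_names_zero_padded(self):
        g = simulate_interactome(SimulationConfig(seed=5, n_nodes=50, model_params={"p": 0.2}))
        assert all(n.startswith("G") and len(n) == 5 for n in g.nodes())

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_interactome(SimulationConfig(graph_model="small_world"))
        with pytest.raises(ValueError):
            simulate_interactome(
                SimulationConfig(n_nodes=10, graph_model="barabasi_albert",
                                 model_params={"m": 20})
            )


class TestPlantModule:
    def test_full_edge_prob_gives_clique(self, er_background):
        net = er_background.copy()
        module = plant_module(net, 12, 1.0, seed=6)
        sub = net.subgraph(module.genes)
        assert sub.number_of_edges() == 12 * 11 // 2

    def test_snowball_connected_without_densification(self, er_background):
        net = er_background.copy()
        module = plant_module(net, 25, 0.0, seed=7)
        assert nx.is_connected(net.subgraph(module.genes))

    def test_densification_increases_edges(self, er_background):
        net = er_background.copy()
        before = net.number_of_edges()
        module = plant_module(net, 30, 0.4, seed=8)
        assert net.number_of_edges() > before
        assert len(module) == 30

    def test_oversized_module_rejected(self, path_graph):
        with pytest.raises(ValueError):
            plant_module(path_graph, 10, 0.5, seed=1)


class TestPlantOverlappingSets:
    def test_full_sharing_gives_identical_sets(self, er_background):
        net = er_background.copy()
        a, b = plant_overlapping_sets(net, 20, 20, shared=20, seed=9)
        assert set(a) == set(b)

    def test_shared_count_exact(self, er_background):
        net = er_background.copy()
        a, b = plant_overlapping_sets(net, 25, 30, shared=10, seed=10)
        assert len(a) == 25 and len(b) == 30
        assert len(set(a) & set(b)) == 10

    def test_mean_separation_decreases_with_sharing(self):
        from netoverlap.proximity import _LccDistances, _set_distances

        means = []
        for shared in (0, 8, 16):
            vals = []
            for s in range(6):
                net = simulate_interactome(
                    SimulationConfig(seed=700 + s, n_nodes=800, model_params={"p": 0.005})
                )
                a, b = plant_overlapping_sets(net, 32, 32, shared, seed=800 + s)
                d = _LccDistances(net)
                ia, ib = d.map_set(a), d.map_set(b)
                da, db, dab = _set_distances(d.matrix, ia, ib, "nearest", True)
                vals.append(dab - (da + db) / 2)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_infeasible_sharing_rejected(self, er_background):
        with pytest.raises(ValueError):
            plant_overlapping_sets(er_background.copy(), 10, 10, shared=11, seed=1)


class TestSimulateExpression:
    def test_null_config_has_no_truth(self):
        cfg = SimulationConfig(seed=11, marker_fold=1.0, n_cell_types=3, cells_per_type=20,
                               model_params={"n_genes": 100, "markers_per_type": 10})
        _, _, truth = simulate_expression(cfg)
        assert truth.empty

    def test_marker_means_elevated_within_type(self):
        cfg = SimulationConfig(seed=12, marker_fold=5.0, n_cell_types=3, cells_per_type=60,
                               model_params={"n_genes": 150, "markers_per_type": 20})
        expr, annot, truth = simulate_expression(cfg)
        for typ in annot.unique():
            markers = truth[truth.marker_of == typ].gene
            inside = expr.loc[markers, annot[annot == typ].index].values.mean()
            outside = expr.loc[markers, annot[annot != typ].index].values.mean()
            assert inside > 2 * outside

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=13, n_cell_types=2, cells_per_type=15,
                               model_params={"n_genes": 60, "markers_per_type": 5})
        e1, a1, t1 = simulate_expression(cfg)
        e2, a2, t2 = simulate_expression(cfg)
        assert (e1.values == e2.values).all()
        assert (a1 == a2).all() and t1.equals(t2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(SimulationConfig(model_params={"mu": -1}))
        with pytest.raises(ValueError):
            simulate_expression(
                SimulationConfig(n_cell_types=4,
                                 model_params={"n_genes": 50, "markers_per_type": 40})
            )


def test_fixture_bundle_writes_all_inputs(tmp_path):
    cfg = SimulationConfig(seed=14, n_nodes=300, module_size=20, n_cell_types=3,
                           cells_per_type=20,
                           model_params={"p": 0.01, "n_genes": 120, "markers_per_type": 10})
    paths = write_fixture_bundle(cfg, tmp_path / "fx")
    for p in paths.values():
        assert p.exists() and p.stat().st_size > 0
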