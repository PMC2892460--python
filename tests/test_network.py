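import math

import numpy as np
import pytest

from pleionet import io as pio
from pleionet.network import (
    build_graph,
    clustering_coefficient,
    compute_centralities,
    disease_interactor_fraction,
)
from _oracles import oracle_centralities, random_connected_graph


def _graph(edges):
    return build_graph(pio.InteractionEdgeList(edges))


class TestBuildGraph:
    def test_dedup_and_self_loops(self):
        G = _graph([("A", "B"), ("B", "A"), ("A", "A"), ("B", "C")])
        assert G.number_of_nodes() == 3
        assert G.number_of_edges() == 2
        assert G.graph["n_self_loops_removed"] == 1
        assert G.graph["n_duplicate_edges_removed"] == 1

    def test_components(self):
        G = _graph([("A", "B"), ("B", "C"), ("C", "A"),
                    ("X", "Y"), ("Y", "Z"), ("Z", "X")])
        assert G.graph["n_components"] == 2
        comp = {n: G.nodes[n]["component"] for n in G}
        assert comp["A"] == comp["B"] == comp["C"]
        assert comp["X"] == comp["Y"] == comp["Z"] != comp["A"]

    def test_single_edge(self):
        G = _graph([("A", "B")])
        assert dict(G.degree()) == {"A": 1, "B": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            _graph([])


class TestCentralities:
    def test_path_graph_hand_counts(self):
        p = compute_centralities(_graph([("A", "B"), ("B", "C")]))
        assert p["degree"].tolist() == [1, 2, 1]
        assert p.loc["A", "closeness"] == pytest.approx(2 / 3)
        assert p.loc["B", "closeness"] == pytest.approx(1.0)
        assert p["betweenness"].tolist() == pytest.approx([0.0, 1.0, 0.0])
        assert p["eccentricity"].tolist() == [2, 1, 2]

    def test_star_graph(self):
        p = compute_centralities(_graph([("c", "l1"), ("c", "l2"), ("c", "l3")]))
        assert p.loc["c", "betweenness"] == pytest.approx(1.0)
        assert p.loc["l1", "betweenness"] == 0.0
        assert p.loc["c", "eccentricity"] == 1
        assert p.loc["l1", "eccentricity"] == 2
        assert p.loc["c", "clustering"] == 0.0

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n, edges = random_connected_graph(rng)
            profile = compute_centralities(_graph([(f"n{a}", f"n{b}")
                                                   for a, b in edges]))
            expected = oracle_centralities(edges, list(range(n)))
            for i in range(n):
                row = profile.loc[f"n{i}"]
                exp = expected[i]
                assert row["degree"] == exp["degree"]
                assert row["closeness"] == pytest.approx(exp["closeness"], abs=1e-9)
                assert row["betweenness"] == pytest.approx(exp["betweenness"], abs=1e-9)
                assert row["eccentricity"] == exp["eccentricity"]
                if exp["clustering"] is None:
                    assert math.isnan(row["clustering"])
                else:
                    assert row["clustering"] == pytest.approx(exp["clustering"], abs=1e-9)

    def test_disconnected_graph_per_component_measures(self):
        G = _graph([("A", "B"), ("B", "C"), ("X", "Y"), ("Z", "Z")])
        p = compute_centralities(G)
        assert p.loc["Z", "closeness"] == 0.0
        assert p.loc["Z", "eccentricity"] == 0
        assert p.loc["X", "closeness"] == pytest.approx(1.0)
        assert ((p["betweenness"] >= 0) & (p["betweenness"] <= 1)).all()

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(3)
        _, edges = random_connected_graph(rng)
        G = _graph([(f"n{a}", f"n{b}") for a, b in edges])
        p = compute_centralities(G)
        assert p["degree"].sum() == 2 * G.number_of_edges()

    def test_relabeling_permutes_multisets(self):
        rng = np.random.default_rng(7)
        _, edges = random_connected_graph(rng)
        p1 = compute_centralities(_graph([(f"a{a}", f"a{b}") for a, b in edges]))
        p2 = compute_centralities(_graph([(f"zz{a}", f"zz{b}") for a, b in edges]))
        for col in ("degree", "closeness", "betweenness", "eccentricity"):
            assert sorted(p1[col]) == pytest.approx(sorted(p2[col]))

    def test_isolated_node_does_not_perturb_others(self):
        base = compute_centralities(_graph([("A", "B"), ("B", "C"), ("C", "A")]))
        with_iso = compute_centralities(
            _graph([("A", "B"), ("B", "C"), ("C", "A"), ("Q", "Q")]))
        for col in ("degree", "closeness", "betweenness", "eccentricity"):
            assert base[col].tolist() == with_iso.loc[["A", "B", "C"], col].tolist()


class TestClustering:
    def test_triangle_is_one(self):
        cc = clustering_coefficient(_graph([("A", "B"), ("B", "C"), ("C", "A")]))
        assert cc.tolist() == [1.0, 1.0, 1.0]

    def test_one_of_three_neighbor_edges(self):
        G = _graph([("h", "x"), ("h", "y"), ("h", "z"), ("x", "y")])
        cc = clustering_coefficient(G)
        assert cc["h"] == pytest.approx(1 / 3)

    def test_low_degree_undefined_by_default(self):
        cc = clustering_coefficient(_graph([("A", "B"), ("B", "C")]))
        assert math.isnan(cc["A"]) and math.isnan(cc["C"])
        cc0 = clustering_coefficient(_graph([("A", "B"), ("B", "C")]),
                                     undefined_as_zero=True)
        assert cc0["A"] == 0.0


class TestDiseaseInteractorFraction:
    def test_fraction_counts(self):
        G = _graph([("g", "a"), ("g", "b"), ("g", "c"), ("g", "d")])
        f = disease_interactor_fraction(G, pio.GeneSet({"g"}, ""),
                                        pio.GeneSet({"a"}, "disease"))
        assert f["g"] == pytest.approx(0.25)

    def test_all_disease_interactors(self):
        G = _graph([("g", "a"), ("g", "b")])
        f = disease_interactor_fraction(G, pio.GeneSet({"g"}, ""),
                                        pio.GeneSet({"a", "b"}, "disease"))
        assert f["g"] == 1.0

    def test_empty_gene_set_rejected(self):
        G = _graph([("a", "b")])
        with pytest.raises(ValueError):
            disease_interactor_fraction(G, pio.GeneSet(set(), ""), pio.GeneSet({"a"}, ""))

    def test_planted_wiring_bias_recovered(self):
        # disease genes wired preferentially to "shared" genes: shared genes
        # draw 60% of their partners from the disease pool, specific 20%
        rng = np.random.default_rng(9)
        disease = [f"d{i}" for i in range(200)]
        background = [f"b{i}" for i in range(600)]
        shared = [f"sh{i}" for i in range(300)]
        specific = [f"sp{i}" for i in range(300)]
        edges = []
        for g, p_dis in [(s, 0.6) for s in shared] + [(s, 0.2) for s in specific]:
            for _ in range(6):
                pool = disease if rng.random() < p_dis else background
                edges.append((g, pool[int(rng.integers(len(pool)))]))
        G = _graph(edges)
        dset = pio.GeneSet(set(disease), "disease")
        f_shared = disease_interactor_fraction(G, pio.GeneSet(set(shared), ""), dset)
        f_specific = disease_interactor_fraction(G, pio.GeneSet(set(specific), ""), dset)
        from pleionet.stats import mann_whitney
        res = mann_whitney(f_shared.values, f_specific.values)
        assert f_shared.mean() > f_specific.mean()
        assert res.p_value < 0.01
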