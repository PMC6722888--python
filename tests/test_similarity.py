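"""Pearson similarity, parameter clustering and correlation graphs."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_table
from imcprofiler import similarity as simi
from imcprofiler.similarity import (
    SimilarityMatrix,
    cross_condition_similarity,
    edge_bundle_graph,
    hierarchical_order,
    linkage_to_newick,
    mean_block_r,
    pearson_matrix,
)
from imcprofiler.synthetic import MEMBRANE_CD_MARKERS, MITOTIC_TRIO


def brute_force_pearson(m):
    """Two-pass covariance oracle, no shortcuts shared with the implementation."""
    n, p = m.shape
    out = np.empty((p, p))
    means = [sum(m[:, j]) / n for j in range(p)]
    for i in range(p):
        for j in range(p):
            num = sum((m[k, i] - means[i]) * (m[k, j] - means[j]) for k in range(n))
            di = sum((m[k, i] - means[i]) ** 2 for k in range(n)) ** 0.5
            dj = sum((m[k, j] - means[j]) ** 2 for k in range(n)) ** 0.5
            out[i, j] = num / (di * dj)
    return out


class TestPearsonMatrix:
    def test_perfect_anticorrelation(self):
        t = toy_table({"mean_a": [1.0, 2.0, 3.0], "mean_b": [-1.0, -2.0, -3.0]})
        sim = pearson_matrix(t, ["a", "b"])
        assert sim.r("a", "b") == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(sim.values), 1.0)

    def test_hand_computed_proportional_columns(self):
        t = toy_table({"mean_x": [1.0, 2.0, 3.0, 4.0],
                       "mean_y": [2.0, 4.0, 6.0, 8.0],
                       "mean_z": [1.0, 3.0, 2.0, 4.0]})
        sim = pearson_matrix(t, ["x", "y", "z"])
        assert sim.r("x", "y") == pytest.approx(1.0)
        oracle = brute_force_pearson(t[["mean_x", "mean_y", "mean_z"]].to_numpy())
        np.testing.assert_allclose(sim.values, oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_covariance_oracle_to_1e12(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(10, 6))
        t = toy_table({f"mean_p{j}": m[:, j].tolist() for j in range(6)})
        sim = pearson_matrix(t, [f"p{j}" for j in range(6)])
        np.testing.assert_allclose(sim.values, brute_force_pearson(m), atol=1e-12)

    def test_constant_column_is_missing_not_zero(self):
        t = toy_table({"mean_a": [1.0, 2.0, 3.0], "mean_b": [5.0, 5.0, 5.0]})
        sim = pearson_matrix(t, ["a", "b"])
        assert np.isnan(sim.r("a", "b"))
        assert sim.r("b", "b") == 1.0

    def test_too_few_cells_rejected(self):
        t = toy_table({"mean_a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3"):
            pearson_matrix(t, ["a"])

    def test_population_filter_by_class(self):
        t = toy_table({"mean_a": [1.0, 2.0, 3.0, 9.0, 9.0, 9.0]})
        t["pred_class"] = ["m"] * 3 + ["other"] * 3
        sim = pearson_matrix(t, ["a"], population_filter="m")
        assert sim.n_cells == 3


class TestHierarchicalOrder:
    def test_perfectly_correlated_pair_merges_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        t = toy_table({"mean_a": x.tolist(), "mean_b": (2 * x).tolist(),
                       "mean_c": rng.normal(size=20).tolist()})
        sim = pearson_matrix(t, ["a", "b", "c"])
        order, Z = hierarchical_order(sim)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge height
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1

    def test_missing_correlation_names_the_pair(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, np.nan], [np.nan, 1.0]]), 5)
        with pytest.raises(ValueError, match="a.*b"):
            hierarchical_order(sim)

    def test_leaf_order_invariant_to_cell_shuffling(self, rng):
        m = rng.normal(size=(50, 5))
        cols = {f"mean_p{j}": m[:, j].tolist() for j in range(5)}
        t = toy_table(cols)
        perm = rng.permutation(50)
        t2 = t.iloc[perm].reset_index(drop=True)
        names = [f"p{j}" for j in range(5)]
        o1, _ = hierarchical_order(pearson_matrix(t, names))
        o2, _ = hierarchical_order(pearson_matrix(t2, names))
        assert o1 == o2

    def test_newick_string_is_well_formed(self, rng):
        m = rng.normal(size=(30, 4))
        t = toy_table({f"mean_p{j}": m[:, j].tolist() for j in range(4)})
        sim = pearson_matrix(t, [f"p{j}" for j in range(4)])
        _, Z = hierarchical_order(sim)
        nwk = linkage_to_newick(Z, sim.parameters)
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 3  # n-1 internal nodes
        for p in sim.parameters:
            assert p in nwk


class TestPlantedStructure:
    def test_mitotic_trio_forms_one_leaf_block(self, truth_table):
        """The shared latent factor must pull pHistone3/Ki-67/p4E-BP1 together."""
        params = list(MITOTIC_TRIO) + ["Ir191-DNA", "Ir193-DNA", "pH2A.X-S139",
                                       "p53"] + list(MEMBRANE_CD_MARKERS)
        sim = pearson_matrix(truth_table, params,
                             population_filter="pHistone3+")
        order, _ = hierarchical_order(sim)
        positions = sorted(order.index(p) for p in MITOTIC_TRIO)
        assert positions[-1] - positions[0] == 2

    def test_ir_isotopes_are_adjacent_leaves(self, truth_table):
        params = ["Ir191-DNA", "Ir193-DNA", "pH2A.X-S139", "p53", "CD29", "CD81"]
        sim = pearson_matrix(truth_table, params, population_filter="pHistone3+")
        order, _ = hierarchical_order(sim)
        ia, ib = order.index("Ir191-DNA"), order.index("Ir193-DNA")
        assert abs(ia - ib) == 1

    def test_trio_and_cd_factor_structure(self, truth_table):
        params = list(MITOTIC_TRIO) + list(MEMBRANE_CD_MARKERS)
        sim = pearson_matrix(truth_table, params, population_filter="pHistone3+")

        def mean_r(group_a, group_b):
            vals = [sim.r(a, b) for a in group_a for b in group_b if a != b]
            return float(np.mean(vals))

        within_trio = mean_r(MITOTIC_TRIO, MITOTIC_TRIO)
        within_cd = mean_r(MEMBRANE_CD_MARKERS, MEMBRANE_CD_MARKERS)
        across = mean_r(MITOTIC_TRIO, MEMBRANE_CD_MARKERS)
        assert within_trio > 0
        assert across < within_cd


class TestCrossCondition:
    @staticmethod
    def _tables(rng):
        a = toy_table({"mean_x": rng.lognormal(0, 0.4, 120).tolist(),
                       "mean_y": rng.lognormal(1, 0.4, 120).tolist()}, "A")
        return a

    def test_duplicated_condition_cross_block_equals_within_block(self, rng):
        a = self._tables(rng)
        sim = cross_condition_similarity({"A": a, "Acopy": a.copy()}, ["x", "y"])
        k = 2
        within = sim.values[:k, :k]
        cross = sim.values[:k, k:]
        np.testing.assert_allclose(within, cross, atol=1e-12)

    def test_entries_bounded_by_one(self, rng):
        a = self._tables(rng)
        b = toy_table({"mean_x": rng.lognormal(0, 1.2, 80).tolist(),
                       "mean_y": rng.lognormal(0, 0.2, 80).tolist()}, "B")
        sim = cross_condition_similarity({"A": a, "B": b}, ["x", "y"])
        assert np.nanmax(np.abs(sim.values)) <= 1.0

    def test_same_distribution_beats_shape_shifted_distribution(self, rng):
        """Quantile-matched blocks: a replicate condition correlates more with
        the reference than a condition with reshaped (bimodal) marginals."""
        def draws(shifted):
            if shifted:
                x = np.where(rng.random(150) < 0.5,
                             rng.lognormal(0, 0.1, 150), rng.lognormal(2.0, 0.1, 150))
            else:
                x = rng.lognormal(1.0, 0.6, 150)
            return x

        ref = toy_table({"mean_x": draws(False).tolist(),
                         "mean_y": draws(False).tolist()}, "ref")
        rep = toy_table({"mean_x": draws(False).tolist(),
                         "mean_y": draws(False).tolist()}, "rep")
        shift = toy_table({"mean_x": draws(True).tolist(),
                           "mean_y": draws(True).tolist()}, "shift")
        sim = cross_condition_similarity(
            {"ref": ref, "rep": rep, "shift": shift}, ["x", "y"]
        )
        assert mean_block_r(sim, "ref", "rep") > mean_block_r(sim, "ref", "shift")

    def test_unmatched_parameters_rejected(self, rng):
        a = self._tables(rng)
        b = toy_table({"mean_x": rng.normal(size=10).tolist()}, "B")
        with pytest.raises(KeyError, match="y"):
            cross_condition_similarity({"A": a, "B": b}, ["x", "y"])


class TestEdgeBundleGraph:
    def test_all_below_cutoff_gives_empty_graph(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]), 10)
        g = edge_bundle_graph(sim, cutoff=0.3)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}

    def test_planted_strong_pair_is_the_only_edge(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.1
        r[1, 2] = r[2, 1] = -0.5
        g = edge_bundle_graph(SimilarityMatrix(["a", "b", "c"], r, 10))
        assert list(g.edges(data="weight")) == [("a", "b", 0.9)]

    def test_cutoff_is_strict(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.3
        g = edge_bundle_graph(SimilarityMatrix(["a", "b"], r, 10), cutoff=0.3)
        assert g.number_of_edges() == 0

    def test_graph_exports_round_trip(self, tmp_path, rng):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.8
        g = edge_bundle_graph(SimilarityMatrix(["a", "b"], r, 10))
        simi.write_graph(g, json_path=tmp_path / "g.json",
                         graphml_path=tmp_path / "g.graphml")
        import json
        import networkx as nx

        data = json.loads((tmp_path / "g.json").read_text())
        back = nx.node_link_graph(data, edges="links")
        assert set(back.edges) == set(g.edges)
        back2 = nx.read_graphml(tmp_path / "g.graphml")
        assert back2.number_of_edges() == 1
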