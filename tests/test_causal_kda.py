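import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from modnet import causal_kda as ck
from modnet.io_formats import Edge, EdgeTable, ExpressionDataset


def _edges(triples, evidence="dap_seq"):
    return EdgeTable([Edge(s, t, w, 1, evidence) for s, t, w in triples])


class TestGraph:
    def test_cycle_resolved_by_min_weight(self):
        t = _edges([("A", "B", 0.9), ("B", "C", 0.5), ("C", "A", 0.8)])
        g = ck.build_causal_graph(t, ["A", "B", "C"])
        assert g.is_acyclic() and g.n_removed_cycle_edges == 1
        assert not g.graph.has_edge("B", "C")

    def test_non_tf_source_dropped_and_counted(self):
        t = _edges([("A", "B", 0.9), ("X", "B", 0.7)])
        g = ck.build_causal_graph(t, ["A"])
        assert g.n_dropped_nontf == 1 and list(g.graph.edges) == [("A", "B")]

    def test_dag_input_untouched(self, genetics_sim):
        g = ck.build_causal_graph(genetics_sim["priors"], genetics_sim["tfs"])
        assert g.is_acyclic() and g.n_removed_cycle_edges == 0
        assert g.graph.number_of_edges() == len(genetics_sim["priors"].edges)

    def test_empty_priors_rejected(self):
        with pytest.raises(ValueError):
            ck.build_causal_graph(EdgeTable([]), ["A"])

    def test_acyclicity_on_randomized_cyclic_priors(self, rng):
        for _ in range(25):
            nodes = [f"T{i}" for i in range(8)]
            triples = [
                (nodes[int(rng.integers(8))], nodes[int(rng.integers(8))],
                 float(rng.uniform(0.1, 1)))
                for _ in range(25)
            ]
            triples = [(s, t, w) for s, t, w in triples if s != t]
            g = ck.build_causal_graph(_edges(triples), nodes)
            assert g.is_acyclic()


class TestKeyDrivers:
    def test_planted_driver_closed_form_p(self):
        # driver with 15 of 20 module genes among its children, universe 2000
        module = {f"g{i}" for i in range(20)}
        children = [f"g{i}" for i in range(15)] + [f"x{i}" for i in range(5)]
        universe = {f"g{i}" for i in range(20)} | {f"x{i}" for i in range(1980)}
        t = _edges([("D", c, 1.0) for c in children])
        g = ck.build_causal_graph(t, ["D"])
        res = {r.node: r for r in ck.key_driver_scan(g, module, universe, depth=2)}
        expect = sps.hypergeom.sf(14, 2000, 20, 20)
        assert res["D"].p_value == pytest.approx(expect, rel=1e-9)
        assert expect < 1e-6 and res["D"].is_key_driver

    def test_leaf_nodes_flagged_untested(self):
        t = _edges([("A", "B", 1.0)])
        g = ck.build_causal_graph(t, ["A"])
        res = {r.node: r for r in ck.key_driver_scan(g, {"B"}, {"A", "B"}, depth=1)}
        assert not res["B"].tested

    def test_random_tf_not_called_driver(self, genetics_sim):
        truth = genetics_sim["truth"]
        g = ck.build_causal_graph(genetics_sim["priors"], genetics_sim["tfs"])
        cofunc = set(genetics_sim["catalog"].genes(truth.driver_module))
        uni = set(genetics_sim["datasets"][0].gene_ids)
        res = [r for r in ck.key_driver_scan(g, cofunc & uni, uni) if r.tested]
        drivers = {r.node for r in res if r.is_key_driver}
        assert drivers == truth.driver_truth


class TestModuleResponse:
    def _ds(self, values):
        return ExpressionDataset(
            "d", "sp", [f"G{i}" for i in range(values.shape[0])],
            [f"S{j}" for j in range(values.shape[1])], values
        ).validate()

    def test_identical_genes_give_their_profile(self, rng):
        x = rng.standard_normal(80)
        ds = self._ds(np.vstack([x, x, x]))
        s = ck.module_response(ds, ["G0", "G1", "G2"])
        xs = (x - x.mean()) / x.std()
        assert abs(np.corrcoef(s, xs)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_sign_anchor_positive(self, rng):
        X = rng.standard_normal((6, 100)) + rng.standard_normal(100) * 0.8
        ds = self._ds(X)
        s = ck.module_response(ds, [f"G{i}" for i in range(6)])
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        assert np.corrcoef(s, Xs.mean(0))[0, 1] > 0

    def test_recovers_latent_factor(self, rng):
        f = rng.standard_normal(200)
        a = np.sqrt(0.4 / 0.6)  # within-module correlation ~0.4, 20 genes
        X = a * f + rng.standard_normal((20, 200))
        s = ck.module_response(self._ds(X), [f"G{i}" for i in range(20)])
        assert abs(np.corrcoef(s, f)[0, 1]) > 0.95


class TestLearners:
    def test_linear_realizable_function(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        y = X.to_numpy() @ np.array([1.0, -2.0, 0.5, 0.0])
        reps = ck.fit_learners(X, y, seed=0, learners=["linear"])
        assert reps[0].cv_rmse < 1e-8

    def test_null_response_rmse_floor(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 5)))
        y = rng.standard_normal(100)
        reps = ck.fit_learners(X, y, seed=0)
        floor = np.std(y) * 0.85
        assert all(r.cv_rmse >= floor for r in reps)

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 4)))
        y = rng.standard_normal(60)
        r1 = ck.fit_learners(X, y, seed=7, learners=["nearest_neighbour", "tree_ensemble"])
        r2 = ck.fit_learners(X, y, seed=7, learners=["nearest_neighbour", "tree_ensemble"])
        for a, b in zip(r1, r2):
            assert a.fold_rmse == b.fold_rmse
            np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_too_small_n_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError):
            ck.fit_learners(X, rng.standard_normal(10))


class TestShapley:
    def test_efficiency_on_random_nonlinear_model(self, rng):
        def predict(M):
            return np.sin(M[:, 0]) + M[:, 1] * M[:, 2] - 0.5 * M[:, 3] ** 2

        bg = rng.standard_normal((40, 4))
        x = rng.standard_normal(4)
        rep = ck.shapley_exact(predict, x, bg)
        assert abs(rep.phi.sum() - (rep.prediction - rep.baseline)) < 1e-8

    def test_exact_equals_linear_closed_form(self, rng):
        beta = rng.standard_normal(6)
        icpt = 0.7

        def predict(M):
            return M @ beta + icpt

        bg = rng.standard_normal((50, 6))
        x = rng.standard_normal(6)
        exact = ck.shapley_exact(predict, x, bg)
        closed = ck.shapley_linear(beta, icpt, x, bg)
        np.testing.assert_allclose(exact.phi, closed.phi, atol=1e-8)

    def test_dummy_feature_zero(self, rng):
        def predict(M):
            return 3.0 * M[:, 0]

        rep = ck.shapley_exact(predict, rng.standard_normal(3), rng.standard_normal((30, 3)))
        np.testing.assert_allclose(rep.phi[1:], 0.0, atol=1e-12)

    def test_symmetry(self, rng):
        def predict(M):
            return M[:, 0] + M[:, 1]

        x = np.array([1.5, 1.5, 0.0])
        bg = np.zeros((10, 3))
        rep = ck.shapley_exact(predict, x, bg)
        assert rep.phi[0] == pytest.approx(rep.phi[1], abs=1e-12)

    def test_sampling_approximates_exact(self, rng):
        def predict(M):
            return M[:, 0] * M[:, 1] + M[:, 2]

        bg = rng.standard_normal((25, 3))
        x = rng.standard_normal(3)
        exact = ck.shapley_exact(predict, x, bg)
        samp = ck.shapley_sampling(predict, x, bg, n_permutations=400, seed=0)
        np.testing.assert_allclose(samp.phi, exact.phi, atol=4 * samp.se.max() + 0.02)

    def test_feature_cap_enforced(self, rng):
        with pytest.raises(ValueError):
            ck.shapley_exact(lambda M: M.sum(1), rng.standard_normal(13),
                             rng.standard_normal((5, 13)))


class TestRanking:
    def test_single_model_prevalence_binary(self, rng):
        phi = rng.standard_normal((4, 6))
        df = ck.rank_drivers({"m": phi}, [f"f{i}" for i in range(6)], top_k=3)
        assert set(df.prevalence_pct) <= {0.0, 100.0}

    def test_prevalence_arithmetic_6_of_11(self):
        feats = ["hit", "other"]
        phi_by = {}
        for i in range(11):
            phi = np.zeros((1, 2))
            phi[0, 0] = 1.0 if i < 6 else 0.0
            phi[0, 1] = 0.5
            phi_by[f"m{i}"] = phi
        df = ck.rank_drivers(phi_by, feats, top_k=1).set_index("feature")
        assert df.loc["hit", "prevalence_pct"] == 54.5

    def test_planted_driver_tops_ranking(self, genetics_sim):
        truth = genetics_sim["truth"]
        ds = genetics_sim["datasets"][0]
        catalog = genetics_sim["catalog"]
        (driver,) = truth.driver_truth
        rng = np.random.default_rng(3)
        others = [t for t in genetics_sim["tfs"] if t != driver][:7]
        feats = [driver] + others
        X = pd.DataFrame(ds.values[[ds.gene_index(g) for g in feats]].T, columns=feats)
        y = ck.module_response(ds, catalog.genes(truth.driver_module))
        reps = ck.fit_learners(X, y, seed=1, learners=["linear", "penalized_linear",
                                                       "nearest_neighbour"])
        bg = X.to_numpy()[rng.choice(len(X), 25, replace=False)]
        inst = X.to_numpy()[rng.choice(len(X), 4, replace=False)]
        phi_by = {r.name: ck.shap_matrix(r.model.predict, inst, bg) for r in reps}
        df = ck.rank_drivers(phi_by, feats, top_k=3)
        assert df.iloc[0].feature == driver and df.iloc[0].prevalence_pct == 100.0
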