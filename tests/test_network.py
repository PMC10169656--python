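"""Mechanistic model construction: sign-consistent subgraphs, phenotype path
search vs an exhaustive brute-force oracle, circuits, model algebra."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import footprintnet as fn

PHE = "DNA_damage"


def activity_table(signs: dict[str, int], scores: dict[str, float] | None = None):
    idx = pd.Index(sorted(signs), name="protein")
    return pd.DataFrame(
        {"score": [(scores or {}).get(p, float(signs[p])) for p in idx],
         "sign": [signs[p] for p in idx]},
        index=idx,
    )


def brute_force_paths(prior, signs, phenotype, direction, max_len):
    """Independent oracle: enumerate ALL simple paths (with every choice of
    parallel-edge sign) and post-filter by the consistency rule."""
    kept = set()
    g = prior.graph
    if phenotype not in g:
        return kept
    for src, src_sign in signs.items():
        if src not in g:
            continue
        for node_path in nx.all_simple_paths(g, src, phenotype, cutoff=max_len):
            sign_options = []
            for u, v in zip(node_path[:-1], node_path[1:]):
                sign_options.append(sorted({d["sign"] for d in g[u][v].values()}))
            for combo in itertools.product(*sign_options):
                ok = True
                prod = 1
                for v, s in zip(node_path[1:], combo):
                    prod *= s
                    if v != phenotype and v in signs and src_sign * prod != signs[v]:
                        ok = False
                        break
                if ok and src_sign * prod == direction:
                    kept.add((tuple(node_path), tuple(combo)))
    return kept


class TestBuildNaiveNetwork:
    def _prior(self):
        prior = fn.PriorNetwork()
        prior.add_node(PHE, phenotype=True)
        for u, v, s in [("A", "B", 1), ("A", "C", 1), ("A", "D", -1),
                        ("D", PHE, 1), ("A", "A", 1)]:
            prior.add_edge(u, v, s)
        return prior

    def test_sign_consistent_edges_kept(self):
        sub = fn.build_naive_network(activity_table({"A": 1, "B": 1}), self._prior())
        assert {(u, v, s) for u, v, s, _ in sub.edge_list()} == {("A", "B", 1)}

    def test_inconsistent_activation_dropped(self):
        sub = fn.build_naive_network(activity_table({"A": 1, "C": -1}), self._prior())
        assert sub.n_edges == 0

    def test_inhibition_of_inactivated_target_kept(self):
        sub = fn.build_naive_network(activity_table({"A": 1, "D": -1}), self._prior())
        assert {(u, v, s) for u, v, s, _ in sub.edge_list()} == {("A", "D", -1)}

    def test_self_loops_removed_and_unknown_proteins_ignored(self):
        sub = fn.build_naive_network(
            activity_table({"A": 1, "NOT_IN_PRIOR": 1}), self._prior())
        assert "NOT_IN_PRIOR" not in sub.graph.nodes
        assert all(u != v for u, v, *_ in sub.edge_list())

    def test_empty_activities_give_empty_network(self):
        sub = fn.build_naive_network(activity_table({}), self._prior())
        assert len(sub) == 0


class TestConnectToPhenotype:
    def _build(self, edges, signs, direction=1, max_len=4):
        prior = fn.PriorNetwork()
        prior.add_node(PHE, phenotype=True)
        for u, v, s in edges:
            prior.add_edge(u, v, s)
        sub = fn.build_naive_network(activity_table(signs), prior)
        return fn.connect_to_phenotype(sub, prior, PHE, direction, max_len)

    def test_direct_activating_path_kept(self):
        model = self._build([("A", PHE, 1)], {"A": 1})
        assert model.node_set() == {"A", PHE}
        assert model.edge_set() == {("A", PHE, 1)}
        assert len(model.paths) == 1

    def test_inhibiting_edge_cannot_explain_positive_phenotype(self):
        model = self._build([("A", PHE, -1)], {"A": 1})
        assert model.n_nodes == 0 and model.n_edges == 0

    def test_double_negative_path_kept(self):
        model = self._build([("A", "B", -1), ("B", PHE, -1)], {"A": 1})
        assert model.node_set() == {"A", "B", PHE}
        (path,) = model.paths
        assert path.sign == 1

    def test_scored_intermediate_must_match_propagated_sign(self):
        # A(+) -> B with +1 edge propagates +, but B is scored -1: path invalid
        model = self._build([("A", "B", 1), ("B", PHE, 1)], {"A": 1, "B": -1})
        assert model.n_nodes == 0
        # with B scored +1 the same path is valid
        model = self._build([("A", "B", 1), ("B", PHE, 1)], {"A": 1, "B": 1})
        assert model.node_set() == {"A", "B", PHE}

    def test_unscored_intermediates_are_allowed(self):
        model = self._build([("A", "X", 1), ("X", PHE, 1)], {"A": 1})
        assert model.node_set() == {"A", "X", PHE}
        assert model.node_sign("X") == 0

    def test_max_len_bounds_path_length(self):
        chain = [("A", "X1", 1), ("X1", "X2", 1), ("X2", "X3", 1), ("X3", PHE, 1)]
        assert self._build(chain, {"A": 1}, max_len=3).n_nodes == 0
        assert self._build(chain, {"A": 1}, max_len=4).n_nodes == 5

    def test_phenotype_absent_raises(self):
        prior = fn.PriorNetwork()
        prior.add_edge("A", "B", 1)
        sub = fn.build_naive_network(activity_table({"A": 1}), prior)
        with pytest.raises(ValueError):
            fn.connect_to_phenotype(sub, prior, PHE, 1, 4)

    def test_matches_exhaustive_oracle_on_random_priors(self, random_prior):
        for seed in range(25):
            prior = random_prior(seed)
            rng = np.random.default_rng(1000 + seed)
            nodes = [n for n in prior.nodes if n != PHE]
            scored = {n: int(rng.choice([-1, 1]))
                      for n in nodes if rng.random() < 0.5}
            direction = int(rng.choice([-1, 1]))
            sub = fn.build_naive_network(activity_table(scored), prior)
            model = fn.connect_to_phenotype(sub, prior, PHE, direction, max_len=4)
            expected = brute_force_paths(prior, scored, PHE, direction, 4)
            got = {(p.nodes, p.edge_signs) for p in model.paths}
            assert got == expected
            # node and edge sets follow from the kept paths + consistent edges
            exp_nodes = {n for p, _ in expected for n in p}
            assert model.node_set() == exp_nodes
            exp_edges = {(p[i], p[i + 1], c[i]) for p, c in expected
                         for i in range(len(c))}
            exp_edges |= {(u, v, s) for u, v, s, _ in sub.edge_list()
                          if u in exp_nodes and v in exp_nodes}
            assert model.edge_set() == exp_edges

    def test_output_independent_of_node_iteration_order(self, random_prior):
        prior = random_prior(3)
        rng = np.random.default_rng(99)
        nodes = [n for n in prior.nodes if n != PHE]
        scored = {n: int(rng.choice([-1, 1])) for n in nodes[:8]}
        sub = fn.build_naive_network(activity_table(scored), prior)
        m1 = fn.connect_to_phenotype(sub, prior, PHE, 1, 4)
        reversed_table = activity_table(scored).iloc[::-1]
        sub2 = fn.build_naive_network(reversed_table, prior)
        m2 = fn.connect_to_phenotype(sub2, prior, PHE, 1, 4)
        assert m1.paths == m2.paths and m1.edge_set() == m2.edge_set()

    def test_increasing_max_len_never_drops_a_node(self, random_prior):
        for seed in range(8):
            prior = random_prior(seed + 40)
            rng = np.random.default_rng(seed)
            scored = {n: int(rng.choice([-1, 1]))
                      for n in prior.nodes if n != PHE and rng.random() < 0.5}
            sub = fn.build_naive_network(activity_table(scored), prior)
            previous: set[str] = set()
            for max_len in (1, 2, 3, 4, 5):
                model = fn.connect_to_phenotype(sub, prior, PHE, 1, max_len)
                assert previous <= model.node_set()
                previous = model.node_set()

    def test_every_produced_model_validates(self, random_prior):
        for seed in range(15):
            prior = random_prior(seed + 100)
            rng = np.random.default_rng(seed)
            scored = {n: int(rng.choice([-1, 1]))
                      for n in prior.nodes if n != PHE and rng.random() < 0.6}
            sub = fn.build_naive_network(activity_table(scored), prior)
            for direction in (-1, 1):
                model = fn.connect_to_phenotype(sub, prior, PHE, direction, 4)
                assert fn.validate_model(model, max_len=4) == []


class TestExtractCircuit:
    def _model(self, random_prior, seed=5):
        prior = random_prior(seed)
        rng = np.random.default_rng(seed)
        scored = {n: int(rng.choice([-1, 1]))
                  for n in prior.nodes if n != PHE and rng.random() < 0.6}
        sub = fn.build_naive_network(activity_table(scored), prior)
        return fn.connect_to_phenotype(sub, prior, PHE, 1, 4)

    def test_disjoint_gene_set_gives_empty_circuit(self, random_prior):
        model = self._model(random_prior)
        circuit = fn.extract_circuit(model, {"NOWHERE"})
        assert circuit.n_nodes == 0 and circuit.paths == ()

    def test_full_source_set_is_idempotent(self, random_prior):
        model = self._model(random_prior)
        circuit = fn.extract_circuit(model, model.sources())
        assert circuit.node_set() == model.node_set()
        assert circuit.edge_set() == model.edge_set()
        assert circuit.paths == model.paths

    def test_circuit_is_always_a_submodel(self, random_prior):
        for seed in range(10):
            model = self._model(random_prior, seed + 7)
            sources = sorted(model.sources())
            if not sources:
                continue
            subset = set(sources[: max(1, len(sources) // 2)])
            circuit = fn.extract_circuit(model, subset)
            assert circuit.edge_set() <= model.edge_set()
            assert circuit.node_set() <= model.node_set()
            assert set(circuit.paths) <= set(model.paths)
            assert fn.validate_model(circuit) == []


class TestModelDiff:
    def test_identical_models_have_no_unique_elements(self, random_prior):
        prior = random_prior(2)
        rng = np.random.default_rng(2)
        scored = {n: int(rng.choice([-1, 1]))
                  for n in prior.nodes if n != PHE and rng.random() < 0.6}
        sub = fn.build_naive_network(activity_table(scored), prior)
        m = fn.connect_to_phenotype(sub, prior, PHE, 1, 4)
        out = fn.model_diff(m, m)
        assert out["nodes_only_a"] == out["nodes_only_b"] == []
        assert out["edges_only_a"] == out["edges_only_b"] == []

    def test_matches_naive_set_arithmetic(self, random_prior):
        models = []
        for seed in (11, 12):
            prior = random_prior(seed)
            rng = np.random.default_rng(seed)
            scored = {n: int(rng.choice([-1, 1]))
                      for n in prior.nodes if n != PHE and rng.random() < 0.6}
            sub = fn.build_naive_network(activity_table(scored), prior)
            models.append(fn.connect_to_phenotype(sub, prior, PHE, 1, 4))
        a, b = models
        out = fn.model_diff(a, b)
        assert set(out["nodes_only_a"]) == a.node_set() - b.node_set()
        assert set(out["nodes_shared"]) == a.node_set() & b.node_set()
        assert set(out["edges_only_b"]) == b.edge_set() - a.edge_set()
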