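import math
from itertools import product

import numpy as np
import pytest

from bnmmi import (
    BayesianNetwork,
    Cpt,
    DagStructure,
    ScoreConfig,
    cpdag,
    family_score,
    fit_parameters,
    hill_climb,
    joint_probability,
    network_score,
    skeleton,
)

from conftest import make_dataset
from test_graphs import all_dags


def brute_force_family_loglik(ds, child, parents):
    """Oracle: enumerate configurations and sum count * log(conditional MLE)."""
    frame = ds.frame
    ll = 0.0
    configs = (
        frame.groupby(list(parents)).groups.items()
        if parents
        else [((), frame.index)]
    )
    for _, idx in configs:
        sub = frame.loc[idx, child]
        total = len(sub)
        for _, cnt in sub.value_counts().items():
            ll += cnt * math.log(cnt / total)
    return ll


def bic_penalty(ds, child, parents):
    q = 1
    for p in parents:
        q *= len(ds.levels[p])
    return 0.5 * math.log(ds.n) * (len(ds.levels[child]) - 1) * q


@pytest.fixture
def three_var(rng):
    # X -> Y strongly, Z independent
    n = 400
    x = rng.integers(0, 2, n)
    y = np.where(rng.random(n) < 0.85, x, 1 - x)
    z = rng.integers(0, 2, n)
    return make_dataset({"x": x, "y": y, "z": z})


class TestFamilyScore:
    def test_single_binary_closed_form(self):
        ds = make_dataset({"x": [0] * 5 + [1] * 5})
        score = family_score(ds, "x", [])
        expected = 10 * math.log(0.5) - 0.5 * math.log(10)
        assert score == pytest.approx(expected, abs=1e-9)
        assert score == pytest.approx(-8.08276, abs=1e-5)

    def test_independent_parent_lowers_bic(self):
        # perfectly balanced independent pair: likelihood gain is exactly 0
        ds = make_dataset(
            {"x": [0, 0, 1, 1] * 250, "y": [0, 1, 0, 1] * 250}
        )
        assert family_score(ds, "y", ["x"]) < family_score(ds, "y", [])

    def test_matches_brute_force_enumeration(self, three_var):
        for child in three_var.variables:
            for parents in ([], ["x"], ["x", "z"], ["y", "z"]):
                if child in parents:
                    continue
                expected = brute_force_family_loglik(
                    three_var, child, parents
                ) - bic_penalty(three_var, child, parents)
                assert family_score(three_var, child, parents) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_child_in_parents_rejected(self, three_var):
        with pytest.raises(ValueError):
            family_score(three_var, "x", ["x"])

    def test_single_level_child_warns(self):
        ds = make_dataset({"a": ["k"] * 10, "b": [0, 1] * 5})
        with pytest.warns(UserWarning, match="single level"):
            score = family_score(ds, "a", ["b"])
        assert score == pytest.approx(0.0)


class TestNetworkScore:
    def test_empty_graph_is_sum_of_marginals(self, three_var):
        dag = DagStructure.from_arcs(three_var.variables)
        total = sum(family_score(three_var, v, []) for v in three_var.variables)
        assert network_score(three_var, dag) == pytest.approx(total)

    def test_score_equivalent_two_node(self, three_var):
        nodes = three_var.variables
        fwd = DagStructure.from_arcs(nodes, [("x", "y")])
        bwd = DagStructure.from_arcs(nodes, [("y", "x")])
        assert network_score(three_var, fwd) == pytest.approx(
            network_score(three_var, bwd), abs=1e-9
        )

    @pytest.mark.parametrize("score_name", ["bic", "bdeu"])
    def test_markov_equivalent_dags_score_equal(self, three_var, score_name):
        """All 25 three-node DAGs: equal CPDAG implies equal score."""
        cfg = ScoreConfig(score_name=score_name)
        dags = all_dags(three_var.variables)
        scores = {d: network_score(three_var, d, cfg) for d in dags}
        for d1 in dags:
            for d2 in dags:
                if cpdag(d1) == cpdag(d2):
                    assert scores[d1] == pytest.approx(scores[d2], abs=1e-8)

    def test_node_mismatch_rejected(self, three_var):
        dag = DagStructure.from_arcs(("x", "y"))
        with pytest.raises(ValueError, match="match"):
            network_score(three_var, dag)


class TestHillClimb:
    def test_balanced_independent_pair_stays_empty(self):
        ds = make_dataset({"x": [0, 0, 1, 1] * 250, "y": [0, 1, 0, 1] * 250})
        assert hill_climb(ds).arcs == frozenset()

    def test_strong_dependence_recovers_skeleton_and_optimum(self, rng):
        n = 1000
        x = rng.integers(0, 2, n)
        y = np.where(rng.random(n) < 0.9, x, 1 - x)
        ds = make_dataset({"x": x, "y": y})
        learned = hill_climb(ds)
        assert skeleton(learned) == {frozenset("xy")}
        best = max(
            network_score(ds, d) for d in all_dags(("x", "y"))
        )
        assert network_score(ds, learned) == pytest.approx(best, abs=1e-9)

    def test_attains_exhaustive_optimum_on_three_nodes(self, three_var):
        learned = hill_climb(three_var)
        best = max(network_score(three_var, d) for d in all_dags(three_var.variables))
        assert network_score(three_var, learned) == pytest.approx(best, abs=1e-9)

    def test_local_optimality(self, three_var):
        """No single add/delete/reverse improves the returned structure."""
        cfg = ScoreConfig()
        learned = hill_climb(three_var, cfg)
        base = network_score(three_var, learned, cfg)
        nodes = sorted(learned.nodes)
        neighbors = []
        for p in nodes:
            for c in nodes:
                if p == c:
                    continue
                if (p, c) in learned.arcs:
                    neighbors.append(learned.arcs - {(p, c)})
                    neighbors.append((learned.arcs - {(p, c)}) | {(c, p)})
                elif (c, p) not in learned.arcs:
                    neighbors.append(learned.arcs | {(p, c)})
        for arcs in neighbors:
            try:
                dag = DagStructure.from_arcs(nodes, arcs)
            except ValueError:
                continue
            assert network_score(three_var, dag, cfg) <= base + cfg.improvement_epsilon

    def test_deterministic(self, three_var):
        assert hill_climb(three_var) == hill_climb(three_var)

    def test_recovery_rate_with_strong_effects(self):
        """Two-node, n=500, odds ratio far above 5: near-certain recovery."""
        hits = 0
        reps = 100
        for j in range(reps):
            r = np.random.default_rng([7, j])
            x = r.integers(0, 2, 500)
            y = np.where(r.random(500) < 0.9, x, 1 - x)  # OR = 81
            ds = make_dataset({"x": x, "y": y})
            learned = hill_climb(ds)
            best = max(network_score(ds, d) for d in all_dags(("x", "y")))
            hits += network_score(ds, learned) == pytest.approx(best, abs=1e-9)
        assert hits >= 99

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hill_climb(make_dataset({"a": [], "b": []}))

    def test_single_variable_returns_empty_graph(self):
        ds = make_dataset({"a": [0, 1, 0]})
        dag = hill_climb(ds)
        assert dag.nodes == {"a"} and dag.arcs == frozenset()


class TestFitParameters:
    def test_posterior_mean_closed_form(self):
        ds = make_dataset({"x": [0, 0, 0, 1]})
        bn = fit_parameters(ds, DagStructure.from_arcs("x"), prior_weight=1.0)
        # counts (3,1), cell prior 0.5 -> (3.5/5, 1.5/5)
        assert bn.cpts["x"].table[0] == pytest.approx([0.7, 0.3])

    def test_unobserved_parent_config_uniform(self):
        ds = make_dataset(
            {"p": ["0", "0"], "c": ["0", "1"]},
            levels={"p": ("0", "1"), "c": ("0", "1")},
        )
        dag = DagStructure.from_arcs("pc", [("p", "c")])
        bn = fit_parameters(ds, dag, prior_weight=1.0)
        # parent config p=1 never observed -> prior-only posterior
        assert bn.cpts["c"].table[1] == pytest.approx([0.5, 0.5])

    def test_rows_sum_to_one(self, three_var):
        dag = hill_climb(three_var)
        bn = fit_parameters(three_var, dag)
        for cpt in bn.cpts.values():
            assert np.allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_generator_conditionals_at_large_n(self):
        from bnmmi import generate_complete

        ds = generate_complete(n=100_000, seed=5)
        dag = DagStructure.from_arcs(
            ds.variables,
            [("tumor_type", "operation"), ("operation", "twoweeks")],
        )
        bn = fit_parameters(ds, dag)
        cpt = bn.cpts["operation"]
        p_op_malignant = cpt.probability(
            {"tumor_type": "1", "operation": "1"}
        )
        assert p_op_malignant == pytest.approx(0.62, abs=0.01)


class TestJointProbability:
    def chain_network(self):
        nodes = ("T", "O", "W")
        dag = DagStructure.from_arcs(nodes, [("T", "O"), ("O", "W")])
        b = ("0", "1")
        cpts = {
            "T": Cpt("T", (), b, (), [[0.42, 0.58]]),
            "O": Cpt("O", ("T",), b, (b,), [[0.11, 0.89], [0.38, 0.62]]),
            "W": Cpt("W", ("O",), b, (b,), [[0.65, 0.35], [0.51, 0.49]]),
        }
        return BayesianNetwork(dag, cpts)

    def test_chain_product(self):
        bn = self.chain_network()
        p = joint_probability(bn, {"T": "1", "O": "1", "W": "0"})
        assert p == pytest.approx(0.58 * 0.62 * 0.51, abs=1e-12)

    def test_normalization(self):
        bn = self.chain_network()
        total = sum(
            joint_probability(bn, dict(zip("TOW", combo)))
            for combo in product("01", repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_isolated_node_factorizes(self):
        nodes = ("M", "X")
        dag = DagStructure.from_arcs(nodes)
        b = ("0", "1")
        bn = BayesianNetwork(
            dag,
            {
                "M": Cpt("M", (), b, (), [[0.9, 0.1]]),
                "X": Cpt("X", (), b, (), [[0.3, 0.7]]),
            },
        )
        assert joint_probability(bn, {"M": "1", "X": "0"}) == pytest.approx(
            0.1 * 0.3
        )

    def test_partial_assignment_rejected(self):
        bn = self.chain_network()
        with pytest.raises(ValueError, match="every node"):
            joint_probability(bn, {"T": "1", "O": "1"})

    def test_cpt_row_sum_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Cpt("x", (), ("0", "1"), (), [[0.5, 0.6]])


def test_score_config_validation():
    with pytest.raises(ValueError):
        ScoreConfig(score_name="aic")
    with pytest.raises(ValueError):
        ScoreConfig(improvement_epsilon=0)
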