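"""Gene-tree explainer: permutation, BN learning, blanket search, recovery."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import mmxai
from mmxai.ggt import (AssignmentError, BayesNet, GgtConfig,
                       PermutationConfig, bfs_class_variables,
                       discretize_tertiles, ggt_run, joint_probability,
                       learn_parameters, learn_structure, permute_features)


# --------------------------------------------------------------------------
# Permutation generation
# --------------------------------------------------------------------------

def test_zero_epsilon_returns_input_exactly():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((10, 20))
    out = permute_features(X, PermutationConfig(epsilon=0.0, n_permutations=3, seed=1))
    assert len(out) == 3
    for perm in out:
        assert np.array_equal(perm, X)


def test_jitter_is_uniform_on_the_epsilon_interval():
    X = np.zeros((50, 200))
    (perm,) = permute_features(X, PermutationConfig(epsilon=0.5, n_permutations=1, seed=2))
    dev = perm.ravel()
    # KS against U(-0.5, 0.5); 1% critical value ~ 1.63 / sqrt(n)
    ks = stats.kstest(dev, stats.uniform(loc=-0.5, scale=1.0).cdf).statistic
    assert ks < 1.63 / np.sqrt(dev.size)
    assert dev.min() >= -0.5 and dev.max() <= 0.5


def test_permutations_deterministic_per_seed():
    X = np.arange(12, dtype=float).reshape(3, 4)
    cfg = PermutationConfig(epsilon=0.2, n_permutations=2, seed=7)
    a = permute_features(X, cfg)
    b = permute_features(X, PermutationConfig(epsilon=0.2, n_permutations=2, seed=7))
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_non_numeric_matrix_is_type_error():
    with pytest.raises(TypeError):
        permute_features(np.array([["a", "b"]]), PermutationConfig())


def test_invalid_permutation_config_rejected():
    with pytest.raises(ValueError):
        PermutationConfig(epsilon=1.5).validate()
    with pytest.raises(ValueError):
        PermutationConfig(n_permutations=0).validate()


# --------------------------------------------------------------------------
# Structure learning
# --------------------------------------------------------------------------

def test_deterministic_copy_yields_an_edge():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 3, 500)
    data = np.column_stack([a, a])
    dag = learn_structure(data, ["u", "v"], seed=0)
    assert dag.number_of_edges() == 1


def test_independent_variables_rarely_gain_edges():
    rates = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 3, size=(1000, 8))
        dag = learn_structure(data, seed=seed)
        rates.append(dag.number_of_edges() / (8 * 7 / 2))
    assert np.mean(rates) <= 0.05


def test_structure_beats_empty_graph_score_and_is_acyclic():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, 400)
    b = (a + rng.integers(0, 2, 400)) % 3
    data = np.column_stack([a, b, rng.integers(0, 3, 400)])
    dag = learn_structure(data, seed=1)
    assert nx.is_directed_acyclic_graph(dag)
    from mmxai.ggt import _FamilyScorer

    fam = _FamilyScorer(data, data.max(axis=0) + 1)
    empty_score = sum(fam(v, ()) for v in range(data.shape[1]))
    assert dag.graph["score"] >= empty_score - 1e-9


def test_constant_column_is_isolated_with_warning():
    rng = np.random.default_rng(0)
    data = np.column_stack([rng.integers(0, 3, 200), np.zeros(200, dtype=int)])
    with pytest.warns(UserWarning, match="constant"):
        dag = learn_structure(data, ["x", "const"], seed=0)
    assert dag.degree("const") == 0


def test_structure_learning_deterministic_per_seed():
    rng = np.random.default_rng(5)
    data = rng.integers(0, 3, size=(300, 6))
    g1 = learn_structure(data, seed=9)
    g2 = learn_structure(data, seed=9)
    assert sorted(g1.edges) == sorted(g2.edges)


def test_planted_drivers_form_the_class_blanket():
    """Structure learning over screened genes recovers the planted parents."""
    from mmxai.ggt import _screen_genes

    hits = 0
    for seed in range(5):
        cfg = mmxai.ExpressionSimConfig(n_genes=200, n_samples=500,
                                        edge_strength=2.0, seed=seed)
        matrix, labels, _ = mmxai.gen_expression(cfg)
        y = (labels == "AD").astype(int)
        screened = _screen_genes(matrix, y, 50, seed)
        codes, _ = discretize_tertiles(matrix.loc[screened].to_numpy())
        table = np.vstack([codes, y[None, :]]).T
        dag = learn_structure(table, list(screened) + ["class"], seed=seed)
        hits += set(bfs_class_variables(dag, "class")) == {"CTAGE6", "F8A2", "SAMD7"}
    assert hits >= 4


# --------------------------------------------------------------------------
# Parameter learning and joint probability
# --------------------------------------------------------------------------

def test_single_binary_node_empirical_frequency():
    dag = nx.DiGraph()
    dag.add_node("x")
    cpts = learn_parameters(dag, np.array([[1], [1], [1], [0]]), ["x"], pseudocount=0)
    assert cpts["x"]["table"][0, 1] == pytest.approx(0.75)


def test_pseudocount_only_gives_uniform_cpts():
    dag = nx.DiGraph()
    dag.add_edge("a", "b")
    cpts = learn_parameters(dag, np.zeros((0, 2), dtype=int), ["a", "b"],
                            pseudocount=1, cards={"a": 2, "b": 3})
    assert np.allclose(cpts["a"]["table"], 0.5)
    assert np.allclose(cpts["b"]["table"], 1 / 3)


def test_cpt_rows_always_sum_to_one():
    rng = np.random.default_rng(1)
    data = rng.integers(0, 3, size=(100, 4))
    dag = learn_structure(data, seed=0)
    cpts = learn_parameters(dag, data)
    for entry in cpts.values():
        assert np.allclose(entry["table"].sum(axis=1), 1.0, atol=1e-9)


def random_binary_net(n_nodes: int, seed: int) -> BayesNet:
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_nodes)]
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.4:
                dag.add_edge(names[i], names[j])
    cards = {v: 2 for v in names}
    cpts = {}
    for v in names:
        pa = tuple(sorted(dag.predecessors(v)))
        rows = int(np.prod([cards[q] for q in pa])) if pa else 1
        p1 = rng.uniform(0.05, 0.95, size=rows)
        cpts[v] = {"parents": pa, "table": np.column_stack([1 - p1, p1])}
    return BayesNet(dag=dag, cpts=cpts, cards=cards)


def test_two_node_chain_joint_is_product_of_factors():
    dag = nx.DiGraph()
    dag.add_edge("A", "B")
    cpts = {"A": {"parents": (), "table": np.array([[0.4, 0.6]])},
            "B": {"parents": ("A",), "table": np.array([[0.7, 0.3], [0.5, 0.5]])}}
    bn = BayesNet(dag=dag, cpts=cpts, cards={"A": 2, "B": 2})
    assert joint_probability(bn, {"A": 1, "B": 1}) == pytest.approx(0.3)


def test_joint_sums_to_one_over_full_assignment_lattice():
    import itertools

    for seed in range(10):
        n = 2 + seed % 4  # up to 5 binary nodes
        bn = random_binary_net(n, seed)
        total = sum(
            joint_probability(bn, dict(zip(sorted(bn.cards), combo)))
            for combo in itertools.product((0, 1), repeat=n)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_edgeless_net_joint_equals_product_of_marginals():
    bn = random_binary_net(3, 2)
    bn.dag.remove_edges_from(list(bn.dag.edges))
    for v in bn.cpts:
        bn.cpts[v] = {"parents": (), "table": bn.cpts[v]["table"][:1]}
    assignment = {"V0": 1, "V1": 0, "V2": 1}
    expected = np.prod([bn.cpts[v]["table"][0, assignment[v]] for v in assignment])
    assert joint_probability(bn, assignment) == pytest.approx(expected)


def test_missing_variable_is_assignment_error():
    bn = random_binary_net(3, 0)
    with pytest.raises(AssignmentError):
        joint_probability(bn, {"V0": 0, "V1": 1})


# --------------------------------------------------------------------------
# Markov-blanket BFS
# --------------------------------------------------------------------------

def test_blanket_hand_case():
    # A -> C <- B, C -> D, E -> D; blanket of C is {A, B, D, E}
    dag = nx.DiGraph([("A", "C"), ("B", "C"), ("C", "D"), ("E", "D")])
    assert bfs_class_variables(dag, "C") == ["A", "B", "D", "E"]


def test_isolated_target_has_empty_blanket():
    dag = nx.DiGraph([("A", "B")])
    dag.add_node("T")
    assert bfs_class_variables(dag, "T") == []


def test_unknown_target_is_lookup_error():
    with pytest.raises(LookupError):
        bfs_class_variables(nx.DiGraph([("A", "B")]), "Z")


def test_blanket_matches_set_algebra_on_random_dags():
    """Independent oracle: u is in the blanket iff u->t, t->u, or u and t
    share a child; checked edge-by-edge without any traversal."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        names = [f"V{i}" for i in range(n)]
        dag = nx.DiGraph()
        dag.add_nodes_from(names)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    dag.add_edge(names[i], names[j])
        target = names[int(rng.integers(0, n))]
        edges = set(dag.edges)
        oracle = {
            u for u in names if u != target and (
                (u, target) in edges or (target, u) in edges
                or any((u, w) in edges and (target, w) in edges for w in names)
            )
        }
        assert set(bfs_class_variables(dag, target)) == oracle


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

def test_planted_drivers_survive_permutation_stability_selection():
    matrix, labels, _ = mmxai.gen_expression(mmxai.ExpressionSimConfig(
        n_genes=200, n_samples=300, edge_strength=2.0, seed=11))
    report = ggt_run(matrix, labels, GgtConfig(epsilon=0.1, n_permutations=10,
                                               seed=11, restarts=1))
    for driver in ("CTAGE6", "F8A2", "SAMD7"):
        assert report.frequencies[driver] >= 0.9
        assert driver in report.selected_genes


def test_null_expression_selects_nothing_stably():
    matrix, labels, _ = mmxai.gen_expression(mmxai.ExpressionSimConfig(
        n_genes=200, n_samples=300, edge_strength=0.0, seed=12))
    report = ggt_run(matrix, labels, GgtConfig(epsilon=0.1, n_permutations=20,
                                               seed=12, restarts=1))
    assert max(report.frequencies.values(), default=0.0) <= 0.3


def test_ggt_run_deterministic_and_exports_valid_graph():
    matrix, labels, _ = mmxai.gen_expression(mmxai.ExpressionSimConfig(
        n_genes=80, n_samples=150, seed=13))
    cfg = GgtConfig(n_permutations=3, seed=13, n_screen=20, restarts=1)
    r1 = ggt_run(matrix, labels, cfg)
    r2 = ggt_run(matrix, labels, cfg)
    assert r1.to_json() == r2.to_json()
    assert mmxai.validate(r1.graph) == []
    assert nx.is_directed_acyclic_graph(r1.bayesnet.dag)


def test_ggt_run_reads_tsv_files(tmp_path):
    from mmxai.synthetic_data import write_expression_tsv

    matrix, labels, _ = mmxai.gen_expression(mmxai.ExpressionSimConfig(
        n_genes=40, n_samples=60, seed=14))
    path = tmp_path / "expr.tsv"
    write_expression_tsv(matrix, labels, path)
    report = ggt_run(path, config=GgtConfig(n_permutations=2, seed=14,
                                            n_screen=10, restarts=1))
    assert len(report.screened_genes) == 10
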