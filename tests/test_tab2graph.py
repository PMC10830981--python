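"""Tabular graph builder: adjacency algebra, GNN layers, sampling, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mmxai
from mmxai.tab2graph import (AdjacencyMatrix, DimensionError, EmbeddingMatrix,
                             FitError, SamplingError, TabGraphModel,
                             _init_params, _loss_and_grads, build_adjacency,
                             fit_tab_model, gnn_forward, predict,
                             sample_links, tabular_to_graph)


def make_model(W_l, W_r, layer_weights, embedding):
    return TabGraphModel(W_l=np.asarray(W_l, float), W_r=np.asarray(W_r, float),
                         layer_weights=[np.asarray(W, float) for W in layer_weights],
                         embedding=embedding,
                         head_W=np.zeros((embedding.values.shape[1], 2)),
                         head_b=np.zeros(2))


# --------------------------------------------------------------------------
# Adjacency (probability matrix over columns)
# --------------------------------------------------------------------------

def test_single_column_adjacency_is_one():
    E = EmbeddingMatrix(np.array([[0.3, -1.2]]), ["only"])
    model = make_model([[2.0]], [[-1.0]], [], E)
    A = build_adjacency(E, model)
    assert np.allclose(A.values, [[1.0]])


def test_zero_embedding_gives_uniform_rows():
    E = EmbeddingMatrix(np.zeros((4, 3)), list("abcd"))
    model = make_model(np.eye(4), np.eye(4), [], E)
    A = build_adjacency(E, model)
    assert np.allclose(A.values, 0.25)


def test_adjacency_hand_case_matches_direct_formula_evaluation():
    # independent direct evaluation of row-softmax(sig(Wl E) sig(Wr E)^T)
    # for E = I2, Wl = Wr = I2: off-diagonal logit sig(1)sig(0)+sig(0)sig(1),
    # diagonal logit sig(1)^2 + sig(0)^2; frozen values below
    E = EmbeddingMatrix(np.eye(2), ["x1", "x2"])
    model = make_model(np.eye(2), np.eye(2), [], E)
    A = build_adjacency(E, model).values
    expected = np.array([[0.5133438473587731, 0.4866561526412268],
                         [0.4866561526412268, 0.5133438473587731]])
    assert np.allclose(A, expected, atol=1e-12)


def test_adjacency_shape_mismatch_names_expected_dimension():
    E = EmbeddingMatrix(np.zeros((3, 2)), list("abc"))
    model = make_model(np.eye(2), np.eye(2), [], E)
    with pytest.raises(DimensionError) as err:
        build_adjacency(E, model)
    assert "m=3" in str(err.value)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_adjacency_rows_always_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    m, d = int(rng.integers(1, 6)), int(rng.integers(1, 5))
    E = EmbeddingMatrix(rng.standard_normal((m, d)) * 3, [f"c{i}" for i in range(m)])
    model = make_model(rng.standard_normal((m, m)), rng.standard_normal((m, m)), [], E)
    A = build_adjacency(E, model)
    assert np.allclose(A.values.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(A.values >= 0)


def test_permuting_columns_permutes_adjacency_identically():
    rng = np.random.default_rng(1)
    m, d = 5, 3
    E_vals = rng.standard_normal((m, d))
    W_l, W_r = rng.standard_normal((m, m)), rng.standard_normal((m, m))
    perm = np.array([3, 0, 4, 1, 2])
    E = EmbeddingMatrix(E_vals, [f"c{i}" for i in range(m)])
    A = build_adjacency(E, make_model(W_l, W_r, [], E)).values
    Ep = EmbeddingMatrix(E_vals[perm], [f"c{i}" for i in perm])
    Ap = build_adjacency(Ep, make_model(W_l[np.ix_(perm, perm)],
                                        W_r[np.ix_(perm, perm)], [], Ep)).values
    assert np.allclose(Ap, A[np.ix_(perm, perm)], atol=1e-12)


# --------------------------------------------------------------------------
# GNN layers
# --------------------------------------------------------------------------

def test_zero_layer_weights_make_gnn_identity():
    rng = np.random.default_rng(0)
    E0 = EmbeddingMatrix(rng.standard_normal((3, 4)), list("abc"))
    A = AdjacencyMatrix(np.full((3, 3), 1 / 3))
    for K in (1, 2, 5):
        model = make_model(np.eye(3), np.eye(3), [np.zeros((4, 4))] * K, E0)
        out = gnn_forward(E0, A, model)
        assert np.array_equal(out, E0.values)


def test_gnn_single_layer_hand_case():
    # E1 = E0 + relu(A E0 W1) computed by hand with integer matrices
    E0 = EmbeddingMatrix(np.array([[1.0, 2.0], [0.0, 1.0]]), ["a", "b"])
    A = AdjacencyMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
    W1 = np.array([[1.0, 0.0], [1.0, 1.0]])
    model = make_model(np.eye(2), np.eye(2), [W1], E0)
    out = gnn_forward(E0, A, model)
    assert np.allclose(out, [[3.0, 3.5], [2.0, 2.5]])


def test_gnn_nonfinite_intermediate_names_layer():
    E0 = EmbeddingMatrix(np.full((2, 2), 1e200), ["a", "b"])
    A = AdjacencyMatrix(np.full((2, 2), 0.5))
    model = make_model(np.eye(2), np.eye(2),
                       [np.full((2, 2), 1e200), np.eye(2)], E0)
    with pytest.raises(FloatingPointError) as err:
        gnn_forward(E0, A, model)
    assert "layer 0" in str(err.value)


# --------------------------------------------------------------------------
# Link sampling
# --------------------------------------------------------------------------

def test_sample_size_zero_gives_empty_pairs():
    assert sample_links(np.ones(4), 0, seed=0).pairs == []


def test_one_hot_row_always_samples_its_column():
    row = np.array([0.0, 0.0, 1.0, 0.0])
    sample = sample_links(row, 50, seed=3, row_index=7)
    assert sample.pairs == [(7, 2)] * 50


def test_uniform_row_frequencies_within_three_standard_errors():
    m, s = 5, 10_000
    sample = sample_links(np.ones(m), s, seed=11)
    counts = np.bincount([j for _, j in sample.pairs], minlength=m)
    se = np.sqrt((1 / m) * (1 - 1 / m) / s)
    assert np.all(np.abs(counts / s - 1 / m) < 3 * se)


def test_all_zero_row_is_sampling_error():
    with pytest.raises(SamplingError):
        sample_links(np.zeros(3), 2, seed=0)


def test_sampling_deterministic_per_seed():
    row = np.array([0.2, 0.5, 0.3])
    assert sample_links(row, 20, seed=9).pairs == sample_links(row, 20, seed=9).pairs


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def test_analytic_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5, 3))
    y = np.array([0, 1, 0, 1, 1])
    params = _init_params(3, 2, 2, 1)
    params["Wh"] = rng.standard_normal((2, 2))
    params["bh"] = rng.standard_normal(2)
    _, grads, _ = _loss_and_grads(params, X, y)
    eps = 1e-6

    def numeric(arr):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up, *_ = _loss_and_grads(params, X, y)
            arr[idx] = orig - eps
            dn, *_ = _loss_and_grads(params, X, y)
            arr[idx] = orig
            g[idx] = (up - dn) / (2 * eps)
        return g

    for name in ("B", "W_l", "W_r", "Wh", "bh"):
        assert np.allclose(numeric(params[name]), grads[name], atol=1e-7), name
    for k in range(2):
        assert np.allclose(numeric(params["Wk"][k]), grads["Wk"][k], atol=1e-7)


@pytest.fixture(scope="module")
def strong_cohort():
    return mmxai.gen_tabular(mmxai.TabularCohortConfig(n_patients=400, seed=3))[0]


def test_training_loss_nonincreasing_and_seed_deterministic(strong_cohort):
    m1 = fit_tab_model(strong_cohort, seed=0, epochs=40)
    m2 = fit_tab_model(strong_cohort, seed=0, epochs=40)
    assert m1.loss_history == m2.loss_history
    assert all(a >= b - 1e-12 for a, b in zip(m1.loss_history, m1.loss_history[1:]))


def test_heldout_accuracy_beats_080_on_strong_effects():
    from sklearn.model_selection import train_test_split

    accs = []
    for seed in range(10):
        table, _ = mmxai.gen_tabular(mmxai.TabularCohortConfig(n_patients=400, seed=seed))
        tr, te = train_test_split(np.arange(len(table)), test_size=0.25,
                                  random_state=seed, stratify=table["class"])
        model = fit_tab_model(table.iloc[tr], seed=seed, epochs=120)
        acc = (predict(model, table.iloc[te])
               == table.iloc[te]["class"].to_numpy()).mean()
        accs.append(acc)
    assert np.mean(accs) > 0.8


def test_permuted_labels_train_to_chance(strong_cohort):
    from sklearn.model_selection import train_test_split

    accs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        table = strong_cohort.copy()
        table["class"] = rng.permutation(table["class"].to_numpy())
        tr, te = train_test_split(np.arange(len(table)), test_size=0.25,
                                  random_state=seed, stratify=table["class"])
        model = fit_tab_model(table.iloc[tr], seed=seed, epochs=60)
        accs.append((predict(model, table.iloc[te])
                     == table.iloc[te]["class"].to_numpy()).mean())
    assert 0.4 <= np.mean(accs) <= 0.6


def test_single_class_labels_is_fit_error(strong_cohort):
    table = strong_cohort.copy()
    table["class"] = "demented"
    with pytest.raises(FitError):
        fit_tab_model(table, seed=0, epochs=5)


def test_dominant_feature_attracts_most_adjacency_mass():
    """A single informative column should receive the largest attention mass.

    The adjacency is row-stochastic, so attention received (column mass) is
    the discriminating quantity.
    """
    eff = {k: 0.0 for k in ("age", "sex", "mental_state", "clinical_dementia",
                            "normalized_brain_volume", "intracranial_volume")}
    eff["mental_state"] = -8.0
    hits = 0
    for seed in range(10):
        table, _ = mmxai.gen_tabular(mmxai.TabularCohortConfig(
            n_patients=300, effect_sizes=eff, seed=seed))
        model = fit_tab_model(table, seed=seed, epochs=100)
        A = build_adjacency(model.embedding, model).values
        top = model.embedding.column_names[int(np.argmax(A.sum(axis=0)))]
        hits += top == "mental_state"
    assert hits >= 8


# --------------------------------------------------------------------------
# Graph assembly
# --------------------------------------------------------------------------

def test_graph_has_one_entity_per_column_and_merged_duplicates(strong_cohort):
    model = fit_tab_model(strong_cohort, seed=0, epochs=30)
    graph = tabular_to_graph(strong_cohort, model, s=2, seed=0)
    m = len(model.embedding.column_names)
    assert len(graph.entities) == m
    assert len(graph.triples) <= 2 * m
    assert all(cat == "feature" for cat in graph.categories.values())
    assert mmxai.validate(graph) == []
    A = build_adjacency(model.embedding, model).values
    names = model.embedding.column_names
    for h, _, t, w in graph.triples:
        assert w == pytest.approx(A[names.index(h), names.index(t)])


def test_near_one_hot_rows_link_only_to_argmax_partner():
    # a saturated adjacency concentrates every row's samples on its argmax
    rng = np.random.default_rng(0)
    E = EmbeddingMatrix(np.eye(3) * 60.0, list("abc"))
    model = make_model(rng.standard_normal((3, 3)), rng.standard_normal((3, 3)),
                       [], E)
    A = build_adjacency(E, model).values
    for i in range(3):
        j_star = int(np.argmax(A[i]))
        if A[i, j_star] > 0.999:
            sample = sample_links(A[i], 30, seed=i, row_index=i)
            assert set(sample.pairs) == {(i, j_star)}
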