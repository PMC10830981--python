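"""Knowledge-graph construction from tabular data.

The table's m columns are represented by a learned embedding matrix
E in R^{m x d}.  A probability adjacency matrix over columns is

    A = softmax( sigma(W_l E) sigma(W_r E)^T ),    W_l, W_r in R^{m x m},

with sigma the sigmoid and softmax applied row-wise, so every row of A is a
probability distribution over linked columns.  (The trainable matrices are
square in m and therefore multiply the embedding on the left; that is the
only dimensionally consistent placement once d != m.)

Per-sample feature matrices are refined by K graph-convolution layers with a
residual connection to the initial embedding at every layer:

    E_k = E_0 + relu(A E_{k-1} W_k),    W_k in R^{d x d}.

Training (supervised on the demented / non-demented label) mean-pools the
final feature matrix into a linear class head and minimizes cross-entropy by
full-batch gradient descent with a backtracking step size, so the recorded
loss is non-increasing by construction.  Gradients are derived analytically
(see ``_loss_and_grads``); a finite-difference check lives in the test
suite.

Link weights come from row-wise multinomial sampling over A: for column i,
``RowSample(A[i, :], s)`` draws s partner columns and each retained pair
(i, j) becomes a triple (col_i, "interacts", col_j) weighted by A[i, j]
(duplicate draws merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_core import InvalidGraphError, KnowledgeGraph, validate

INTERACTS = "interacts"


class DimensionError(ValueError):
    """Shape mismatch between an embedding matrix and model weights."""


class NumericError(FloatingPointError):
    """Non-finite value produced inside the forward pass."""


class SamplingError(ValueError):
    """Row weights do not define a valid multinomial distribution."""


class FitError(ValueError):
    """Training preconditions violated (e.g. single-class labels)."""


@dataclass
class EmbeddingMatrix:
    """m x d column-embedding matrix; row j embeds table column j."""

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise DimensionError("embedding must be a 2-D m x d matrix with m, d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise NumericError("embedding contains non-finite entries")
        if len(self.column_names) != self.values.shape[0]:
            raise DimensionError("column_names length must equal m")


@dataclass
class AdjacencyMatrix:
    """Row-stochastic m x m probability adjacency matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != m:
            raise DimensionError("adjacency must be square")
        if np.any(self.values < 0):
            raise ValueError("adjacency entries must be >= 0")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("adjacency rows must sum to 1 within 1e-9")


@dataclass
class TabGraphModel:
    """Trainable parameters of the tabular graph builder.

    ``embedding`` is the column embedding E (m x d); ``W_l``/``W_r`` are the
    m x m adjacency factors; ``layer_weights`` holds the K d x d convolution
    matrices; ``head_W``/``head_b`` form the linear readout.  Preprocessing
    statistics (means/scales per expanded column) ride along so the model can
    be applied to new rows of the same schema.
    """

    W_l: np.ndarray
    W_r: np.ndarray
    layer_weights: list[np.ndarray]
    embedding: EmbeddingMatrix
    head_W: np.ndarray
    head_b: np.ndarray
    activation: str = "relu"
    seed: int = 0
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None
    classes_: list[str] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.embedding.values.shape[0]

    @property
    def d(self) -> int:
        return self.embedding.values.shape[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _row_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_adjacency(E: EmbeddingMatrix, model: TabGraphModel) -> AdjacencyMatrix:
    """Probability adjacency A = row-softmax(sigmoid(W_l E) sigmoid(W_r E)^T)."""
    m = E.values.shape[0]
    if model.W_l.shape != (m, m) or model.W_r.shape != (m, m):
        raise DimensionError(
            f"W_l/W_r must be {m} x {m} to match the embedding's m={m} columns, "
            f"got {model.W_l.shape} and {model.W_r.shape}"
        )
    S_l = _sigmoid(model.W_l @ E.values)
    S_r = _sigmoid(model.W_r @ E.values)
    return AdjacencyMatrix(_row_softmax(S_l @ S_r.T))


def gnn_forward(E0: EmbeddingMatrix, A: AdjacencyMatrix, model: TabGraphModel) -> np.ndarray:
    """Run the K residual graph-convolution layers on one feature matrix.

    Every layer adds relu(A E_{k-1} W_k) on top of the initial matrix E_0,
    so zero layer weights make the whole stack the identity.
    """
    E_prev = E0.values
    out = E_prev
    for k, W_k in enumerate(model.layer_weights):
        if W_k.shape != (E_prev.shape[1], E_prev.shape[1]):
            raise DimensionError(f"layer {k}: W_k must be d x d = {E_prev.shape[1]}")
        with np.errstate(over="ignore", invalid="ignore"):
            out = E0.values + np.maximum(A.values @ E_prev @ W_k, 0.0)
        if not np.all(np.isfinite(out)):
            raise NumericError(f"non-finite values in layer {k}")
        E_prev = out
    return out


@dataclass
class LinkSample:
    """s sampled (i, j) link pairs for one table row of the adjacency."""

    pairs: list[tuple[int, int]]
    sample_size: int


def sample_links(E_row: np.ndarray, s: int, seed: int, row_index: int = 0) -> LinkSample:
    """Draw s partner columns from the multinomial over a (normalized) row."""
    row = np.asarray(E_row, dtype=float)
    if s < 0:
        raise SamplingError("sample size must be >= 0")
    if np.any(row < 0) or not np.all(np.isfinite(row)):
        raise SamplingError("row weights must be finite and non-negative")
    total = row.sum()
    if s > 0 and total <= 0:
        raise SamplingError("all-zero row defines no multinomial distribution")
    if s == 0:
        return LinkSample(pairs=[], sample_size=0)
    rng = np.random.default_rng(seed)
    draws = rng.choice(row.size, size=s, p=row / total)
    return LinkSample(pairs=[(row_index, int(j)) for j in draws], sample_size=s)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def preprocess_table(table: pd.DataFrame, label_col: str = "class"):
    """One-hot expand object columns, return (X, columns, labels or None)."""
    feats = table.drop(columns=[label_col], errors="ignore")
    labels = table[label_col].to_numpy() if label_col in table.columns else None
    feats = pd.get_dummies(feats, dtype=float)
    X = feats.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise FitError("table contains missing values after preprocessing")
    return X, list(feats.columns), labels


def _forward(params: dict, X: np.ndarray):
    """Full forward pass; returns cache for backprop."""
    B = params["B"]
    S_l = _sigmoid(params["W_l"] @ B)
    S_r = _sigmoid(params["W_r"] @ B)
    Z = S_l @ S_r.T
    A = _row_softmax(Z)
    E0 = X[:, :, None] * B[None, :, :]
    Es = [E0]
    caches = []
    E_prev = E0
    for W_k in params["Wk"]:
        P = np.einsum("uv,nvd->nud", A, E_prev)
        Q = np.einsum("nud,de->nue", P, W_k)
        R = np.maximum(Q, 0.0)
        E_k = E0 + R
        caches.append((P, Q))
        Es.append(E_k)
        E_prev = E_k
    pooled = Es[-1].mean(axis=1)
    logits = pooled @ params["Wh"] + params["bh"]
    return {"S_l": S_l, "S_r": S_r, "A": A, "E0": E0, "Es": Es,
            "caches": caches, "pooled": pooled, "logits": logits}


def _loss_and_grads(params: dict, X: np.ndarray, y: np.ndarray):
    """Cross-entropy loss and analytic gradients for every parameter."""
    n, m = X.shape
    fwd = _forward(params, X)
    logits = fwd["logits"]
    probs = _row_softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), y] + eps))

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads = {
        "Wh": fwd["pooled"].T @ dlogits,
        "bh": dlogits.sum(axis=0),
    }
    dpooled = dlogits @ params["Wh"].T
    dE = np.repeat(dpooled[:, None, :] / m, m, axis=1)

    A = fwd["A"]
    dE0 = np.zeros_like(fwd["E0"])
    dA = np.zeros_like(A)
    gWk = [np.zeros_like(W) for W in params["Wk"]]
    for k in range(len(params["Wk"]) - 1, -1, -1):
        P, Q = fwd["caches"][k]
        E_prev = fwd["Es"][k]
        dE0 += dE                       # residual branch
        dQ = dE * (Q > 0)
        gWk[k] = np.einsum("nud,nue->de", P, dQ)
        dP = np.einsum("nue,de->nud", dQ, params["Wk"][k])
        dA += np.einsum("nud,nvd->uv", dP, E_prev)
        dE = np.einsum("uv,nud->nvd", A, dP)
    dE0 += dE                           # gradient reaching E_0 itself

    # B through the per-sample initial matrices E0 = x_j * B_j
    dB = np.einsum("nm,nmd->md", X, dE0)
    # softmax rows: dZ_u = a_u * (dA_u - <a_u, dA_u>)
    dZ = A * (dA - (A * dA).sum(axis=1, keepdims=True))
    dS_l = dZ @ fwd["S_r"]
    dS_r = dZ.T @ fwd["S_l"]
    dU_l = dS_l * fwd["S_l"] * (1.0 - fwd["S_l"])
    dU_r = dS_r * fwd["S_r"] * (1.0 - fwd["S_r"])
    B = params["B"]
    grads["W_l"] = dU_l @ B.T
    grads["W_r"] = dU_r @ B.T
    dB += params["W_l"].T @ dU_l + params["W_r"].T @ dU_r
    grads["B"] = dB
    grads["Wk"] = gWk
    return loss, grads, probs


def _init_params(m: int, d: int, K: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    return {
        "B": rng.standard_normal((m, d)) / np.sqrt(d),
        "W_l": rng.standard_normal((m, m)) / np.sqrt(m),
        "W_r": rng.standard_normal((m, m)) / np.sqrt(m),
        "Wk": [rng.standard_normal((d, d)) / np.sqrt(d) for _ in range(K)],
        "Wh": np.zeros((d, 2)),
        "bh": np.zeros(2),
    }


def fit_tab_model(table: pd.DataFrame, labels=None, *, label_col: str = "class",
                  d: int = 8, K: int = 2, epochs: int = 150,
                  learning_rate: float = 0.5, seed: int = 0) -> TabGraphModel:
    """Train the graph builder end to end on a labeled cohort table.

    Full-batch gradient descent with backtracking (the step is halved until
    the loss does not increase), so ``loss_history`` is non-increasing.
    Deterministic for a fixed seed.
    """
    X, columns, tbl_labels = preprocess_table(table, label_col)
    if labels is None:
        labels = tbl_labels
    if labels is None:
        raise FitError(f"no labels: column {label_col!r} absent and none passed")
    classes = sorted(set(map(str, labels)))
    if len(classes) < 2:
        raise FitError("need at least 2 classes to fit")
    y = np.array([classes.index(str(v)) for v in labels])

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    m = Xs.shape[1]
    params = _init_params(m, d, K, seed)
    history: list[float] = []
    loss, grads, _ = _loss_and_grads(params, Xs, y)
    lr = learning_rate
    for _ in range(epochs):
        history.append(loss)
        step = lr
        for _try in range(20):
            trial = {
                "B": params["B"] - step * grads["B"],
                "W_l": params["W_l"] - step * grads["W_l"],
                "W_r": params["W_r"] - step * grads["W_r"],
                "Wk": [W - step * g for W, g in zip(params["Wk"], grads["Wk"])],
                "Wh": params["Wh"] - step * grads["Wh"],
                "bh": params["bh"] - step * grads["bh"],
            }
            new_loss, new_grads, _ = _loss_and_grads(trial, Xs, y)
            if new_loss <= loss:
                params, loss, grads = trial, new_loss, new_grads
                break
            step *= 0.5
        else:
            break  # no descent direction at machine precision
    history.append(loss)

    model = TabGraphModel(
        W_l=params["W_l"], W_r=params["W_r"], layer_weights=params["Wk"],
        embedding=EmbeddingMatrix(params["B"], columns),
        head_W=params["Wh"], head_b=params["bh"],
        seed=seed, feature_means=mu, feature_scales=sd,
        classes_=classes, loss_history=history,
    )
    return model


def predict_proba(model: TabGraphModel, table: pd.DataFrame, label_col: str = "class") -> np.ndarray:
    """Class probabilities for each row of a table with the trained schema."""
    X, columns, _ = preprocess_table(table, label_col)
    if columns != model.embedding.column_names:
        raise DimensionError("table columns do not match the trained schema")
    Xs = (X - model.feature_means) / model.feature_scales
    params = {"B": model.embedding.values, "W_l": model.W_l, "W_r": model.W_r,
              "Wk": model.layer_weights, "Wh": model.head_W, "bh": model.head_b}
    return _row_softmax(_forward(params, Xs)["logits"])


def predict(model: TabGraphModel, table: pd.DataFrame, label_col: str = "class") -> np.ndarray:
    probs = predict_proba(model, table, label_col)
    return np.array([model.classes_[i] for i in probs.argmax(axis=1)])


def tabular_to_graph(table: pd.DataFrame, model: TabGraphModel, s: int, seed: int,
                     label_col: str = "class") -> KnowledgeGraph:
    """Assemble the column-interaction knowledge graph from a trained model.

    One entity per table column (category ``"feature"``); for each column i,
    s partners are drawn from A's row i and each distinct draw becomes the
    triple (col_i, "interacts", col_j) with weight A[i, j].
    """
    A = build_adjacency(model.embedding, model).values
    names = model.embedding.column_names
    graph = KnowledgeGraph(
        entities=set(names),
        relations={INTERACTS},
        categories={name: "feature" for name in names},
    )
    for i, name in enumerate(names):
        sample = sample_links(A[i], s, seed + i, row_index=i)
        seen: set[int] = set()
        for _, j in sample.pairs:
            if j in seen:
                continue
            seen.add(j)
            graph.triples.append((name, INTERACTS, names[j], float(A[i, j])))
    violations = validate(graph)
    if violations:  # pragma: no cover - construction guarantees validity
        raise InvalidGraphError(violations)
    return graph
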