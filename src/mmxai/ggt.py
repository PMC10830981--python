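"""Graphical gene tree: a Bayesian-network explainer for expression data.

The explainer answers "which genes is the class label directly associated
with?" in three steps:

1. **Permutation generation** — each expression value F_i is jittered
   uniformly on [F_i - eps, F_i + eps] (permutation variance eps in [0, 1]),
   producing ``n_permutations`` replicate matrices.  Replicates drive a
   stability selection: a gene counts only if it keeps being recovered
   under perturbation.
2. **Bayesian-network learning** — on each (discretized) replicate a DAG
   over genes + class is learned by greedy hill climbing with add / delete /
   reverse moves scored by BIC (random restarts, bounded parent count),
   followed by maximum-likelihood CPT estimation with a Laplace
   pseudocount.  The joint factorizes by the chain rule
   P(F_1..F_n) = prod_i P(F_i | Pa(F_i)).
3. **Breadth-first class-variable search** — from the class node, BFS
   collects its parents, children, and the children's other parents: the
   Markov blanket, the minimal set shielding the class from all other
   genes.

Continuous expression is discretized to per-gene tertiles (scale-free)
before network learning, and genes are pre-screened by mutual information
with the class so the structure search runs over a tractable candidate set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .graph_core import KnowledgeGraph
from .synthetic_data import read_expression_tsv

logger = logging.getLogger(__name__)

CLASS_NODE = "class"


class AssignmentError(ValueError):
    """Joint-probability assignment is missing variables or uses bad levels."""


# --------------------------------------------------------------------------
# Permutation generation
# --------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    epsilon: float = 0.1
    n_permutations: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def permute_features(matrix, config: PermutationConfig) -> list:
    """Jitter every value uniformly on [F_i - eps, F_i + eps], per replicate."""
    config.validate()
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix)
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("permute_features requires a numeric matrix")
        values = values.astype(float)
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_permutations):
        jitter = rng.uniform(-config.epsilon, config.epsilon, size=values.shape)
        perm = values + jitter
        if isinstance(matrix, pd.DataFrame):
            perm = pd.DataFrame(perm, index=matrix.index, columns=matrix.columns)
        out.append(perm)
    return out


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------

def discretize_tertiles(matrix: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-row tertile codes {0,1,2} and the bin edges used.

    Rows are variables.  A constant row collapses to a single level (the
    caller isolates such variables).
    """
    values = np.asarray(matrix, dtype=float)
    codes = np.zeros(values.shape, dtype=np.int64)
    edges: list[np.ndarray] = []
    for i, row in enumerate(values):
        cut = np.quantile(row, [1 / 3, 2 / 3])
        codes[i] = np.searchsorted(cut, row, side="right")
        edges.append(cut)
    return codes, edges


# --------------------------------------------------------------------------
# Structure learning: hill climbing with BIC
# --------------------------------------------------------------------------

class _FamilyScorer:
    """Cached BIC family scores over an (n, p) matrix of discrete codes."""

    def __init__(self, data: np.ndarray, cards: np.ndarray):
        self.data = data
        self.cards = cards
        self.n = data.shape[0]
        self.log_n = np.log(self.n)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = parents + (v,)
        dims = self.cards[list(cols)]
        idx = np.ravel_multi_index(tuple(self.data[:, c] for c in cols), dims)
        counts = np.bincount(idx, minlength=int(np.prod(dims))).reshape(-1, dims[-1])
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(counts / row_tot), 0.0).sum()
        q = counts.shape[0]
        score = ll - 0.5 * self.log_n * (dims[-1] - 1) * q
        self._cache[key] = score
        return score


def _reachability(parents: list[set[int]], p: int) -> np.ndarray:
    """Boolean matrix reach[u, v] = path u -> v exists (including u == v)."""
    adj = np.zeros((p, p), dtype=bool)
    for v, pa in enumerate(parents):
        for u in pa:
            adj[u, v] = True
    reach = adj | np.eye(p, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            return reach
        reach = nxt


def _hill_climb(scorer: _FamilyScorer, p: int, active: list[int],
                max_parents: int, init_parents: list[set[int]]):
    parents = [set(s) for s in init_parents]
    node_scores = {v: scorer(v, tuple(sorted(parents[v]))) for v in active}
    while True:
        reach = _reachability(parents, p)
        best_delta = 1e-9
        best_move = None
        for v in active:
            pa = parents[v]
            base = node_scores[v]
            for u in active:
                if u == v:
                    continue
                if u not in pa:
                    # add u -> v; cycle iff v already reaches u
                    if len(pa) < max_parents and not reach[v, u]:
                        delta = scorer(v, tuple(sorted(pa | {u}))) - base
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", u, v)
                else:
                    delta = scorer(v, tuple(sorted(pa - {u}))) - base
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", u, v)
                    # reverse u -> v: cycle iff another path u ~> v survives
                    if len(parents[u]) < max_parents:
                        parents[v].discard(u)
                        other_path = _reachability(parents, p)[u, v]
                        parents[v].add(u)
                        if not other_path:
                            delta = (scorer(v, tuple(sorted(pa - {u}))) - base
                                     + scorer(u, tuple(sorted(parents[u] | {v})))
                                     - node_scores[u])
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            parents[v].add(u)
        elif op == "del":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)
            node_scores[u] = scorer(u, tuple(sorted(parents[u])))
        node_scores[v] = scorer(v, tuple(sorted(parents[v])))
    total = sum(node_scores.values())
    return parents, total


def learn_structure(data: np.ndarray, names: list[str] | None = None, *,
                    scorer: str = "bic", max_parents: int = 3, seed: int = 0,
                    restarts: int = 3) -> nx.DiGraph:
    """Learn a DAG over discrete variables by greedy hill climbing with BIC.

    ``data`` is (n_observations, n_variables) with small non-negative
    integer codes.  Moves are add / delete / reverse with acyclicity checked
    before every application; restart 0 starts from the empty graph and
    further restarts from seeded random DAGs; the best-scoring local
    optimum wins (its score is stored as ``graph.graph["score"]`` and is
    always >= the empty-graph score).  Constant variables are isolated with
    a warning.
    """
    if scorer != "bic":
        raise ValueError(f"unknown scorer {scorer!r}")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    data = np.asarray(data, dtype=np.int64)
    n, p = data.shape
    names = list(names) if names is not None else [f"V{i}" for i in range(p)]
    cards = data.max(axis=0) + 1
    active = [v for v in range(p) if cards[v] >= 2]
    for v in range(p):
        if cards[v] < 2:
            warnings.warn(f"variable {names[v]!r} is constant; isolated in the DAG")
    fam = _FamilyScorer(data, np.maximum(cards, 1))

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            init = [set() for _ in range(p)]
        else:
            order = list(rng.permutation(active))
            init = [set() for _ in range(p)]
            prob = min(1.0, 2.0 / max(1, len(active)))
            for pos, v in enumerate(order):
                for u in order[:pos]:
                    if len(init[v]) < max_parents and rng.random() < prob:
                        init[v].add(u)
        parents, total = _hill_climb(fam, p, active, max_parents, init)
        if best is None or total > best[1] + 1e-12:
            best = (parents, total)

    parents, total = best
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    for v, pa in enumerate(parents):
        for u in pa:
            dag.add_edge(names[u], names[v])
    dag.graph["score"] = float(total)
    return dag


# --------------------------------------------------------------------------
# Parameter learning and inference
# --------------------------------------------------------------------------

@dataclass
class BayesNet:
    """DAG + CPTs over discrete variables (genes and the class).

    ``cpts[v]`` holds ``{"parents": tuple of names, "table": array}`` where
    the table has shape (prod parent cards, card_v) and rows summing to 1.
    """

    dag: nx.DiGraph
    cpts: dict[str, dict]
    cards: dict[str, int]
    discretization: dict[str, np.ndarray] = field(default_factory=dict)


def learn_parameters(dag: nx.DiGraph, data: np.ndarray,
                     names: list[str] | None = None,
                     pseudocount: float = 1.0,
                     cards: dict[str, int] | None = None) -> dict[str, dict]:
    """Estimate every node's CPT from counts plus a Laplace pseudocount.

    Unseen parent configurations fall back to the (uniform) pseudocount
    prior — never an error.  Every row sums to 1.
    """
    data = np.asarray(data, dtype=np.int64)
    p = data.shape[1]
    names = list(names) if names is not None else [f"V{i}" for i in range(p)]
    col = {name: i for i, name in enumerate(names)}
    if cards is None:
        cards = {name: int(data[:, col[name]].max()) + 1 for name in names}
    cpts: dict[str, dict] = {}
    for node in dag.nodes:
        pa = tuple(sorted(dag.predecessors(node)))
        dims = [cards[q] for q in pa] + [cards[node]]
        if data.shape[0] > 0:
            idx = np.ravel_multi_index(
                tuple(data[:, col[q]] for q in pa) + (data[:, col[node]],), dims)
            counts = np.bincount(idx, minlength=int(np.prod(dims))).astype(float)
        else:
            counts = np.zeros(int(np.prod(dims)))
        table = (counts.reshape(-1, dims[-1]) + pseudocount)
        row_tot = table.sum(axis=1, keepdims=True)
        zero_rows = row_tot[:, 0] == 0  # pseudocount 0 and unseen config
        table[zero_rows] = 1.0 / dims[-1]
        row_tot[zero_rows] = 1.0
        cpts[node] = {"parents": pa, "table": table / np.where(row_tot == 0, 1.0, row_tot)}
    return cpts


def joint_probability(bn: BayesNet, assignment: dict[str, int]) -> float:
    """Chain-rule joint: product over nodes of P(node | parents)."""
    prob = 1.0
    for node in bn.dag.nodes:
        if node not in assignment:
            raise AssignmentError(f"assignment missing variable {node!r}")
        entry = bn.cpts[node]
        level = int(assignment[node])
        if not 0 <= level < bn.cards[node]:
            raise AssignmentError(f"level {level} invalid for {node!r} (card {bn.cards[node]})")
        pa = entry["parents"]
        if pa:
            pa_dims = [bn.cards[q] for q in pa]
            row = int(np.ravel_multi_index(tuple(int(assignment[q]) for q in pa), pa_dims))
        else:
            row = 0
        prob *= float(entry["table"][row, level])
    return prob


def bfs_class_variables(bn: BayesNet | nx.DiGraph, target_variable: str) -> list[str]:
    """Markov blanket of the target by breadth-first traversal.

    Level 1 visits the target's parents and children; level 2 visits each
    child's other parents.  Returns a sorted (order-stable) list excluding
    the target itself.
    """
    dag = bn.dag if isinstance(bn, BayesNet) else bn
    if target_variable not in dag:
        raise LookupError(f"target {target_variable!r} not in the DAG")
    found: set[str] = set()
    frontier = [target_variable]
    parents = set(dag.predecessors(target_variable))
    children = set(dag.successors(target_variable))
    found |= parents | children
    frontier = sorted(children)
    for child in frontier:  # second BFS level: co-parents
        found |= set(dag.predecessors(child))
    found.discard(target_variable)
    return sorted(found)


# --------------------------------------------------------------------------
# Full GGT pipeline
# --------------------------------------------------------------------------

@dataclass
class GgtConfig:
    epsilon: float = 0.1
    n_permutations: int = 20
    seed: int = 0
    n_screen: int = 50
    max_parents: int = 3
    restarts: int = 3
    pseudocount: float = 1.0
    frequency_threshold: float = 0.5


@dataclass
class GgtReport:
    """Stability-selection outcome over permutation replicates."""

    frequencies: dict[str, float]
    selected_genes: list[str]
    screened_genes: list[str]
    bayesnet: BayesNet
    graph: KnowledgeGraph
    config: GgtConfig

    def to_json(self) -> dict:
        return {
            "frequencies": {g: float(f) for g, f in sorted(self.frequencies.items())},
            "selected_genes": list(self.selected_genes),
            "screened_genes": list(self.screened_genes),
            "epsilon": self.config.epsilon,
            "n_permutations": self.config.n_permutations,
            "seed": self.config.seed,
        }


def _screen_genes(matrix: pd.DataFrame, y: np.ndarray, n_screen: int, seed: int) -> list[str]:
    """Top genes by mutual information with the class (stable tie-break)."""
    X = matrix.to_numpy(dtype=float).T
    mi = mutual_info_classif(X, y, random_state=seed)
    order = np.argsort(-mi, kind="stable")[: min(n_screen, len(mi))]
    return [matrix.index[i] for i in sorted(order)]


def _learn_on_codes(codes: np.ndarray, names: list[str], cfg: GgtConfig, seed: int):
    dag = learn_structure(codes, names, max_parents=cfg.max_parents,
                          seed=seed, restarts=cfg.restarts)
    return dag


def ggt_run(expression, labels=None, config: GgtConfig | None = None) -> GgtReport:
    """Run the full explainer on a genes-by-samples matrix (or TSV path).

    For each permutation replicate: jitter -> tertile discretization ->
    structure learning -> Markov blanket of the class.  Genes are reported
    with their selection frequency across replicates; those at or above
    ``frequency_threshold`` form the selected set.  A reference network
    fitted on the unjittered data is returned along with its knowledge-graph
    export.  Deterministic for a fixed config seed.
    """
    config = config or GgtConfig()
    if isinstance(expression, (str,)) or hasattr(expression, "__fspath__"):
        expression, labels = read_expression_tsv(expression)
    if labels is None:
        raise ValueError("labels are required when passing a matrix directly")
    labels = np.asarray([str(l) for l in labels])
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected a binary label row, got classes {classes}")
    y = (labels == "AD").astype(int) if "AD" in classes else (labels == classes[1]).astype(int)

    screened = _screen_genes(expression, y, config.n_screen, config.seed)
    sub = expression.loc[screened]
    names = list(screened) + [CLASS_NODE]

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_permutations + 1) % (2**31)
    perm_cfg = PermutationConfig(epsilon=config.epsilon,
                                 n_permutations=config.n_permutations,
                                 seed=int(seeds[0]))
    replicates = permute_features(sub, perm_cfg)

    counts: dict[str, int] = {g: 0 for g in screened}
    for r, perm in enumerate(replicates):
        codes, _ = discretize_tertiles(perm.to_numpy())
        table = np.vstack([codes, y[None, :]]).T  # observations x variables
        dag = _learn_on_codes(table, names, config, int(seeds[r + 1]))
        for gene in bfs_class_variables(dag, CLASS_NODE):
            counts[gene] = counts.get(gene, 0) + 1
    frequencies = {g: counts[g] / config.n_permutations for g in screened}
    selected = [g for g in screened if frequencies[g] >= config.frequency_threshold]

    # reference network on the unjittered data
    codes, edges = discretize_tertiles(sub.to_numpy())
    table = np.vstack([codes, y[None, :]]).T
    dag = _learn_on_codes(table, names, config, config.seed)
    cards = {name: int(table[:, i].max()) + 1 for i, name in enumerate(names)}
    cpts = learn_parameters(dag, table, names, pseudocount=config.pseudocount, cards=cards)
    bn = BayesNet(dag=dag, cpts=cpts, cards=cards,
                  discretization={g: e for g, e in zip(screened, edges)})

    graph = KnowledgeGraph(
        entities=set(names),
        relations={"depends_on"},
        triples=[(u, "depends_on", v, 1.0) for u, v in sorted(dag.edges)],
        categories={**{g: "gene" for g in screened}, CLASS_NODE: "class"},
    )
    return GgtReport(frequencies=frequencies, selected_genes=selected,
                     screened_genes=list(screened), bayesnet=bn, graph=graph,
                     config=config)
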