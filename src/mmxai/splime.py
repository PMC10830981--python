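"""Local surrogate explanations (LIME) and submodular pick (SP-LIME).

For a black-box classifier p and an instance x, LIME fits the sparse linear
surrogate

    exp(x) = argmin_f  theta(p, f, lambda_x) + Omega(f),

where theta is a squared loss over perturbations drawn around x, weighted
by the similarity kernel lambda_x = exp(-dist^2 / kernel_width^2), and
Omega caps the surrogate at ``max_features`` non-zero coefficients (the
cap keeps the largest-magnitude standardized weights from an unpenalized
weighted least-squares fit, then refits on that subset).

SP-LIME stacks the n per-instance weight vectors into the explanation
matrix W (n x d), scores each feature's global importance
I_j = sqrt(sum_i |W_ij|), and greedily picks a budget-B set of instances V
maximizing the coverage

    C(V, W, I) = sum_j [exists i in V : W_ij != 0] * I_j .

Coverage is monotone and submodular, so the greedy pick is within a factor
(1 - 1/e) of the optimal subset.

The default black box for cohort tables is a probability-calibrated
support-vector classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic_data import DEMENTED
from .tab2graph import preprocess_table

COVER_TOL = 1e-12  # |W_ij| above this counts as covering feature j


class PredictionError(RuntimeError):
    """The black-box predictor failed on a perturbation batch."""


@dataclass
class LimeConfig:
    n_samples: int = 500
    kernel_width: float = 1.0
    max_features: int = 6
    surrogate: str = "weighted-least-squares"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass
class LimeExplanation:
    weights: np.ndarray          # length-d, zeros outside the selected subset
    intercept: float
    fidelity: float              # weighted R^2 of the surrogate
    used_features: list[int]


def lime_explain(black_box, instance: np.ndarray, config: LimeConfig,
                 feature_scales: np.ndarray | None = None,
                 target_class: int = 1) -> LimeExplanation:
    """Fit the local linear surrogate around one instance.

    ``black_box(X)`` must return class probabilities (n, n_classes) or a
    score vector (n,); the surrogate is fitted to column ``target_class``.
    Perturbations are Gaussian with per-feature sd ``feature_scales``
    (default 1), distances are measured in units of those scales, and the
    fit is weighted least squares under the similarity kernel.
    Deterministic per config seed.
    """
    config.validate()
    x0 = np.asarray(instance, dtype=float)
    d = x0.size
    scales = np.ones(d) if feature_scales is None else np.asarray(feature_scales, dtype=float)
    rng = np.random.default_rng(config.seed)
    X = x0 + rng.standard_normal((config.n_samples, d)) * scales
    try:
        y = np.asarray(black_box(X), dtype=float)
    except Exception as exc:
        raise PredictionError(f"black box failed on the perturbation batch: {exc}") from exc
    if y.ndim == 2:
        y = y[:, target_class]
    dist2 = (((X - x0) / scales) ** 2).sum(axis=1)
    lam = np.exp(-dist2 / config.kernel_width**2)

    def wls(cols: np.ndarray) -> tuple[np.ndarray, float]:
        design = np.column_stack([np.ones(config.n_samples), X[:, cols] - x0[cols]])
        sw = np.sqrt(lam)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        return coef[1:], coef[0]

    all_cols = np.arange(d)
    w_full, _ = wls(all_cols)
    if d > config.max_features:
        importance = np.abs(w_full * scales)
        keep = np.sort(np.argsort(-importance, kind="stable")[: config.max_features])
    else:
        keep = all_cols
    w_sub, intercept = wls(keep)
    weights = np.zeros(d)
    weights[keep] = w_sub

    pred = intercept + (X[:, keep] - x0[keep]) @ w_sub
    resid = ((y - pred) ** 2 * lam).sum()
    ybar = (y * lam).sum() / lam.sum()
    total = ((y - ybar) ** 2 * lam).sum()
    fidelity = 1.0 - resid / total if total > 0 else 1.0
    return LimeExplanation(weights=weights, intercept=float(intercept),
                           fidelity=float(fidelity), used_features=list(map(int, keep)))


# --------------------------------------------------------------------------
# Global importance, coverage, submodular pick
# --------------------------------------------------------------------------

@dataclass
class ExplanationMatrix:
    W: np.ndarray                # n instances x d features
    I: np.ndarray                # length-d global importance
    feature_names: list[str] = field(default_factory=list)


@dataclass
class PickResult:
    V: list[int]
    budget: int
    coverage: float


def global_importance(W: np.ndarray) -> np.ndarray:
    """I_j = sqrt(sum_i |W_ij|) — square-root column mass of |W|."""
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("explanation matrix must be finite")
    return np.sqrt(np.abs(W).sum(axis=0))


def coverage(V, W: np.ndarray, I: np.ndarray) -> float:
    """Importance mass of features touched by at least one picked instance."""
    W = np.asarray(W, dtype=float)
    I = np.asarray(I, dtype=float)
    V = list(V)
    n = W.shape[0]
    for i in V:
        if not 0 <= int(i) < n:
            raise IndexError(f"instance index {i} out of range [0, {n})")
    if not V:
        return 0.0
    covered = (np.abs(W[V]) > COVER_TOL).any(axis=0)
    return float(I[covered].sum())


def submodular_pick(W: np.ndarray, I: np.ndarray, B: int) -> PickResult:
    """Greedy coverage maximization under budget B (ties -> lowest index).

    Monotone submodularity of the coverage guarantees the greedy value is
    at least (1 - 1/e) of the best budget-B subset.  Instances adding zero
    marginal gain are not picked, so |V| can be smaller than B.
    """
    if B < 1:
        raise ValueError("budget B must be >= 1")
    W = np.asarray(W, dtype=float)
    I = np.asarray(I, dtype=float)
    n = W.shape[0]
    picked: list[int] = []
    covered = np.zeros(W.shape[1], dtype=bool)
    value = 0.0
    for _ in range(min(B, n)):
        gains = np.where(np.abs(W) > COVER_TOL, ~covered, False) @ I
        gains[picked] = -np.inf
        best = int(np.argmax(gains))  # argmax takes the lowest index on ties
        if gains[best] <= 0:
            break
        picked.append(best)
        covered |= np.abs(W[best]) > COVER_TOL
        value += float(gains[best])
    return PickResult(V=picked, budget=B, coverage=value)


# --------------------------------------------------------------------------
# Cohort-level report
# --------------------------------------------------------------------------

def train_svc_black_box(table: pd.DataFrame, labels=None, *, label_col: str = "class",
                        seed: int = 0):
    """Probability-calibrated SVC on a cohort table; returns (predict_proba, classes)."""
    X, columns, tbl_labels = preprocess_table(table, label_col)
    y = np.asarray(labels if labels is not None else tbl_labels)
    model = make_pipeline(StandardScaler(),
                          SVC(probability=True, random_state=seed))
    model.fit(X, y)
    classes = list(model.classes_)
    return model.predict_proba, classes


@dataclass
class CohortExplanation:
    ranking: dict[str, list[dict]]   # class label -> [{feature, weight}, ...]
    picked: list[int]
    pick_coverage: float
    matrix: ExplanationMatrix

    def to_json(self) -> dict:
        return {
            "ranking": {cls: [{"feature": e["feature"], "weight": float(e["weight"])}
                              for e in entries]
                        for cls, entries in self.ranking.items()},
            "picked": list(map(int, self.picked)),
            "coverage": float(self.pick_coverage),
        }


def explain_cohort(table: pd.DataFrame, labels=None, black_box=None, *,
                   config: LimeConfig | None = None, budget: int = 5,
                   label_col: str = "class", positive_class: str = DEMENTED,
                   n_explain: int | None = None) -> CohortExplanation:
    """Explain every instance, rank factors per class, pick B exemplars.

    The per-instance surrogate weight is the local slope of the probability
    of ``positive_class``.  For the class-level factor ranking each
    instance's feature contribution is the slope times the instance's
    standardized displacement from the cohort mean (how much that value
    pushes the probability relative to an average patient); a class ranks
    features by the mean contribution toward it over its own instances, so
    e.g. below-average brain volume with a negative slope counts *for* the
    demented class.  Deterministic per config seed.
    """
    config = config or LimeConfig()
    X, feature_names, tbl_labels = preprocess_table(table, label_col)
    y = np.asarray(labels if labels is not None else tbl_labels)
    if black_box is None:
        black_box, classes = train_svc_black_box(table, y, label_col=label_col,
                                                 seed=config.seed)
    else:
        classes = sorted(set(map(str, y)))
    pos_idx = classes.index(positive_class) if positive_class in classes else 1
    neg_label = next((c for c in classes if c != classes[pos_idx]), "other")

    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    n = X.shape[0] if n_explain is None else min(n_explain, X.shape[0])
    W = np.zeros((n, X.shape[1]))
    for i in range(n):
        cfg_i = LimeConfig(n_samples=config.n_samples, kernel_width=config.kernel_width,
                           max_features=config.max_features, seed=config.seed + i)
        exp = lime_explain(black_box, X[i], cfg_i, feature_scales=scales,
                           target_class=pos_idx)
        W[i] = exp.weights * scales  # standardized scale: comparable across features

    I = global_importance(W)
    pick = submodular_pick(W, I, budget)
    # contribution of feature j to instance i's positive-class probability:
    # slope (standardized) times standardized displacement from the mean
    Z = (X[:n] - X.mean(axis=0)) / scales
    contrib = W * Z
    y_n = np.asarray(y[:n])
    pos_mask = y_n == classes[pos_idx]
    ranking = {}
    for cls, mask, sign in ((classes[pos_idx], pos_mask, 1.0),
                            (neg_label, ~pos_mask, -1.0)):
        mean_c = sign * contrib[mask].mean(axis=0) if mask.any() else np.zeros(W.shape[1])
        order = np.argsort(-mean_c, kind="stable")
        ranking[cls] = [{"feature": feature_names[j], "weight": float(mean_c[j])}
                        for j in order]
    matrix = ExplanationMatrix(W=W, I=I, feature_names=feature_names)
    return CohortExplanation(ranking=ranking, picked=pick.V,
                             pick_coverage=pick.coverage, matrix=matrix)
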