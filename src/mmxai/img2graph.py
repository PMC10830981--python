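"""Region detection, pairwise relations, and knowledge graphs from images.

Pipeline (mirroring a scene-graph construction over brain-slice phantoms):

1. :func:`detect_rois` — a lightweight built-in blob detector (smooth,
   background-subtract, threshold, connected components, moment-based box
   estimation, greedy non-maximum suppression).  It satisfies the detector
   contract and is pluggable: any callable returning the same ROI records
   can stand in for it, e.g. a learned region-proposal model.
2. :func:`score_relations` — a relation probability y_{i->j} for every
   ordered ROI pair from a fixed logistic score on pairwise geometry
   (center proximity, box overlap, intensity correlation); the joint score
   is the product over per-ROI class factors and per-pair relation factors,
   so it lies in [0, 1] and is invariant to ROI ordering.
3. :func:`build_image_graph` — one entity per ROI (category = argmax class
   label); a triple of weight alpha = y_{i->j} per ordered pair, with the
   complementary clause weight 1 - alpha kept as entity metadata.

The module also hosts :class:`SmallCnn`, a from-scratch convolutional
classifier (conv / relu / max-pool / avg-pool / flatten / dense layers with
explicit forward and backward passes).  Keeping the layer algebra explicit
is what lets the relevance-propagation module redistribute its output score
exactly, layer by layer.

Coordinates are 0-based, half-open, row-major everywhere:
box = (row_min, col_min, row_max, col_max).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .graph_core import KnowledgeGraph
from .synthetic_data import IMAGE_CLASS_LABELS


class FitError(ValueError):
    """Classifier training preconditions violated."""


Box = tuple[int, int, int, int]


@dataclass
class Roi:
    """A detected region: box, per-class scores, pooled features."""

    box: Box
    class_scores: dict[str, float]
    feature_vector: np.ndarray

    def class_label(self) -> str:
        return max(self.class_scores, key=lambda k: self.class_scores[k])

    def class_factor(self) -> float:
        return float(max(self.class_scores.values()))

    def to_json(self) -> dict:
        return {"box": list(map(int, self.box)),
                "scores": {k: float(v) for k, v in self.class_scores.items()}}


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open boxes."""
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[2], b[2])
    c1 = min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


@dataclass
class DetectorConfig:
    """Built-in blob detector parameters.

    ``threshold`` defaults to max(0.08, 5 * estimated noise sd) above the
    median background.  ``classifier``, if given, is called on each ROI crop
    to produce class scores; otherwise scores are uniform over
    ``class_labels``.
    """

    smooth_sigma: float = 1.0
    threshold: float | None = None
    min_area: int = 4
    nms_iou: float = 0.3
    class_labels: tuple = IMAGE_CLASS_LABELS
    classifier: Callable[[np.ndarray], dict[str, float]] | None = None


# E[x^2] of a standard normal truncated at +/-3 is 0.97333 sigma^2, so the
# intensity-weighted sample sd of a 3-sigma-truncated Gaussian blob
# underestimates sigma by sqrt(0.97333).
_TRUNC3_SD_CORRECTION = 1.0 / np.sqrt(1.0 - 6.0 * 0.004431848 / 0.9973002)


def detect_rois(image: np.ndarray, config: DetectorConfig | None = None) -> list[Roi]:
    """Detect blob-like regions; returns [] for blank/degenerate images.

    Boxes are estimated from intensity-weighted second moments of each
    connected component (half-extent = 3 estimated sigma), matching the
    3-sigma ground-truth convention of the phantom generator.
    """
    config = config or DetectorConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        return []
    h, w = img.shape
    sm = ndimage.gaussian_filter(img, config.smooth_sigma)
    bg = float(np.median(sm))
    resp = np.clip(sm - bg, 0.0, None)
    noise = 1.4826 * float(np.median(np.abs(sm - bg)))
    thr = config.threshold if config.threshold is not None else max(0.08, 5.0 * noise)
    mask = resp > thr
    labeled, n_comp = ndimage.label(mask)
    comps = []
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labeled == comp)
        if rows.size < config.min_area:
            continue
        peak_at = np.argmax(resp[rows, cols])
        comps.append((rows, cols, (int(rows[peak_at]), int(cols[peak_at]))))
    peaks = np.array([c[2] for c in comps]) if comps else np.empty((0, 2))
    candidates: list[tuple[float, Box, np.ndarray]] = []
    for ci, (rows, cols, peak_rc) in enumerate(comps):
        # expand the component's bbox to capture the blob's full halo
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        er, ec = r1 - r0, c1 - c0
        wr0 = max(0, r0 - er)
        wr1 = min(h, r1 + er)
        wc0 = max(0, c0 - ec)
        wc1 = min(w, c1 + ec)
        win = resp[wr0:wr1, wc0:wc1]
        weights = np.clip(win - 2.0 * noise, 0.0, None)
        if len(comps) > 1:
            # keep only pixels nearer this blob's peak than any other peak,
            # so a neighbor's halo cannot inflate the moment estimates
            gy, gx = np.mgrid[wr0:wr1, wc0:wc1]
            d_own = (gy - peak_rc[0]) ** 2 + (gx - peak_rc[1]) ** 2
            others = np.delete(peaks, ci, axis=0)
            d_other = np.min((gy[..., None] - others[:, 0]) ** 2
                             + (gx[..., None] - others[:, 1]) ** 2, axis=-1)
            weights = np.where(d_own <= d_other, weights, 0.0)
        total = weights.sum()
        if total <= 0:
            continue
        gy, gx = np.mgrid[wr0:wr1, wc0:wc1]
        cy = float((weights * gy).sum() / total)
        cx = float((weights * gx).sum() / total)
        sig_r = np.sqrt((weights * (gy - cy) ** 2).sum() / total) * _TRUNC3_SD_CORRECTION
        sig_c = np.sqrt((weights * (gx - cx) ** 2).sum() / total) * _TRUNC3_SD_CORRECTION
        half_r = max(3.0 * sig_r, 1.0)
        half_c = max(3.0 * sig_c, 1.0)
        box = (max(0, int(round(cy - half_r))), max(0, int(round(cx - half_c))),
               min(h, int(round(cy + half_r)) + 1), min(w, int(round(cx + half_c)) + 1))
        peak = float(np.clip(resp[rows, cols].max(), 0.0, 1.0))
        feats = np.array([rows.size, peak, cy, cx, sig_r, sig_c])
        candidates.append((peak, box, feats))

    # greedy non-maximum suppression, highest score first
    candidates.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, Box, np.ndarray]] = []
    for cand in candidates:
        if all(box_iou(cand[1], k[1]) <= config.nms_iou for k in kept):
            kept.append(cand)

    rois = []
    uniform = {lab: 1.0 / len(config.class_labels) for lab in config.class_labels}
    for peak, box, feats in kept:
        if config.classifier is not None:
            crop = img[box[0]:box[2], box[1]:box[3]]
            scores = config.classifier(crop)
        else:
            scores = dict(uniform)
        rois.append(Roi(box=box, class_scores=scores, feature_vector=feats))
    return rois


# --------------------------------------------------------------------------
# Pairwise relations
# --------------------------------------------------------------------------

@dataclass
class RelationTable:
    """Relation probability per ordered ROI pair plus the joint score.

    The joint score is the maximized probability of the full assignment:
    the product of each ROI's class factor and every ordered pair's
    relation factor.  All factors lie in [0, 1], hence so does the score.
    """

    probs: dict[tuple[int, int], float]
    joint_score: float

    @staticmethod
    def from_factors(class_factors: list[float],
                     pair_probs: dict[tuple[int, int], float]) -> "RelationTable":
        joint = float(np.prod(class_factors)) if class_factors else 1.0
        for p in pair_probs.values():
            joint *= p
        return RelationTable(probs=dict(pair_probs), joint_score=joint)


# fixed proximity-dominant logistic weights for the relation score
_REL_W_PROX, _REL_W_IOU, _REL_W_CORR = 1.5, 2.0, 1.0


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _crop_resized(image: np.ndarray, box: Box, size: int = 8) -> np.ndarray:
    crop = image[box[0]:box[2], box[1]:box[3]]
    if crop.size == 0:
        return np.zeros((size, size))
    return resize(crop, (size, size), anti_aliasing=False)


def relation_probability(roi_i: Roi, roi_j: Roi, image: np.ndarray) -> float:
    """Logistic score on pairwise geometry: proximity, overlap, correlation."""
    h, w = image.shape
    diag = float(np.hypot(h, w))
    ci = ((roi_i.box[0] + roi_i.box[2]) / 2.0, (roi_i.box[1] + roi_i.box[3]) / 2.0)
    cj = ((roi_j.box[0] + roi_j.box[2]) / 2.0, (roi_j.box[1] + roi_j.box[3]) / 2.0)
    dist_norm = np.hypot(ci[0] - cj[0], ci[1] - cj[1]) / diag
    iou = box_iou(roi_i.box, roi_j.box)
    a = _crop_resized(image, roi_i.box).ravel()
    b = _crop_resized(image, roi_j.box).ravel()
    if a.std() > 1e-12 and b.std() > 1e-12:
        corr = float(np.corrcoef(a, b)[0, 1])
    else:
        corr = 0.0
    logit = _REL_W_PROX * (1.0 - 2.0 * dist_norm) + _REL_W_IOU * iou + _REL_W_CORR * corr
    return _sigmoid(logit)


def score_relations(rois: list[Roi], image: np.ndarray) -> RelationTable:
    """Relation probability for every ordered ROI pair and the joint score.

    With a single ROI the pair table is empty and the joint score is the
    product of class factors alone.
    """
    if not rois:
        raise ValueError("score_relations requires at least one ROI")
    pair_probs: dict[tuple[int, int], float] = {}
    for i in range(len(rois)):
        for j in range(len(rois)):
            if i != j:
                pair_probs[(i, j)] = relation_probability(rois[i], rois[j], image)
    return RelationTable.from_factors([r.class_factor() for r in rois], pair_probs)


@dataclass
class TripleWeights:
    """Per-ROI record (roi id, joint probability P_x, connection weight alpha)."""

    entries: list[tuple[str, float, float]]


ALPHA_FLOOR = 1e-6  # triples below this weight carry vanishing clause mass
RELATED_TO = "related_to"


def build_image_graph(rois: list[Roi], relations: RelationTable) -> KnowledgeGraph:
    """Assemble the ROI knowledge graph.

    Entity ``roi_i`` gets category = argmax class label.  Each ordered pair
    (i, j) with relation probability alpha >= 1e-6 contributes a directed
    triple of weight alpha; the complementary clause weight 1 - alpha for
    every pair rooted at i is stored (JSON) in the entity's description,
    together with its box and P_x, the product of the ROI's class factor
    with its pairwise factors.
    """
    names = [f"roi_{i}" for i in range(len(rois))]
    graph = KnowledgeGraph(entities=set(names), relations={RELATED_TO})
    for i, roi in enumerate(rois):
        graph.categories[names[i]] = roi.class_label()
        p_x = roi.class_factor()
        clauses = {}
        for (a, b), alpha in relations.probs.items():
            if a == i:
                p_x *= alpha
                clauses[names[b]] = 1.0 - alpha
        graph.descriptions[names[i]] = json.dumps(
            {"box": list(map(int, roi.box)), "P_x": p_x, "clause_weights": clauses},
            sort_keys=True)
    for (i, j), alpha in sorted(relations.probs.items()):
        if alpha >= ALPHA_FLOOR:
            graph.triples.append((names[i], RELATED_TO, names[j], float(alpha)))
    return graph


# --------------------------------------------------------------------------
# Small CNN: explicit layers with forward/backward
# --------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward/relevance propagation needs."""

    params: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-mode convolution, weights (F, C, kh, kw), bias (F)."""

    params = ("W", "b")

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        self.W = rng.standard_normal((out_channels, in_channels, kernel, kernel)) / np.sqrt(fan_in)
        self.b = np.zeros(out_channels)
        self.kernel = kernel

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (n, C, Ho, Wo, k, k) -> (n, Ho, Wo, C*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(
            x.shape[0], x.shape[2] - k + 1, x.shape[3] - k + 1, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        self.cols = self._cols(x)
        Wmat = self.W.reshape(self.W.shape[0], -1)
        out = self.cols @ Wmat.T + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dmat = dout.transpose(0, 2, 3, 1)  # (n, Ho, Wo, F)
        Wmat = self.W.reshape(self.W.shape[0], -1)
        self.dW = np.einsum("nhwf,nhwc->fc", dmat, self.cols).reshape(self.W.shape)
        self.db = dmat.sum(axis=(0, 1, 2))
        dcols = dmat @ Wmat  # (n, Ho, Wo, C*k*k)
        return self._fold(dcols)

    def _fold(self, dcols: np.ndarray) -> np.ndarray:
        n, Ho, Wo, _ = dcols.shape
        C, k = self.W.shape[1], self.kernel
        dcols = dcols.reshape(n, Ho, Wo, C, k, k)
        dx = np.zeros_like(self.x)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class MaxPool2D(Layer):
    def __init__(self, size: int):
        self.size = size

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        return x.reshape(n, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // s, w // s, s * s)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        win = self._windows(x)
        self.argmax = win.argmax(axis=-1)
        return win.max(axis=-1)

    def _scatter(self, vals: np.ndarray) -> np.ndarray:
        n, c, ho, wo = vals.shape
        s = self.size
        out = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(out, self.argmax[..., None], vals[..., None], axis=-1)
        return out.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(self.x_shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self._scatter(dout)


class AvgPool2D(Layer):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        n, c, h, w = x.shape
        s = self.size
        return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.size
        return np.repeat(np.repeat(dout, s, axis=2), s, axis=3) / (s * s)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.x_shape)


class Dense(Layer):
    params = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self.x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


@dataclass
class SmallCnn:
    """A small image classifier built from the explicit layers above."""

    layers: list
    class_labels: tuple = IMAGE_CLASS_LABELS
    seed: int = 0
    input_shape: tuple = (32, 32)
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    holdout_accuracy: float | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def trainable(self) -> list[Layer]:
        return [l for l in self.layers if l.params]


def default_architecture(input_shape=(32, 32), n_classes=4, seed=0) -> list[Layer]:
    """conv5x6 - relu - maxpool2 - conv3x8 - relu - global avgpool - dense.

    The global average pool gives the head a count-like summary of the
    blob-detector feature maps (per-channel mass), which is the signal the
    phantom severity labels encode.
    """
    rng = np.random.default_rng(seed)
    h, w = input_shape
    h1, w1 = (h - 4) // 2, (w - 4) // 2        # after conv5 + maxpool2
    h2, w2 = h1 - 2, w1 - 2                    # after conv3
    return [
        Conv2D(1, 6, 5, rng), ReLU(), MaxPool2D(2),
        Conv2D(6, 8, 3, rng), ReLU(), AvgPool2D(h2 if h2 == w2 else 1),
        Flatten(), Dense(8 * (1 if h2 == w2 else h2 * w2), n_classes, rng),
    ]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def train_classifier(images: np.ndarray, labels, hyperparams: dict | None = None) -> SmallCnn:
    """Train the small CNN on phantom images with a stratified 75/25 split.

    ``hyperparams`` keys (all optional): epochs (default 12), learning_rate
    (3e-3, Adam), batch_size (32), seed (0), train_fraction (0.75),
    class_labels.  Deterministic per seed; the held-out accuracy is stored
    on the returned model.
    """
    hp = dict(hyperparams or {})
    seed = int(hp.get("seed", 0))
    epochs = int(hp.get("epochs", 12))
    lr = float(hp.get("learning_rate", 3e-3))
    batch_size = int(hp.get("batch_size", 32))
    train_fraction = float(hp.get("train_fraction", 0.75))

    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise FitError("images must be a (n, H, W) array of uniform size")
    labels = np.asarray([str(l) for l in labels])
    class_labels = tuple(hp.get("class_labels", sorted(set(labels))))
    if len(class_labels) < 2:
        raise FitError("need at least 2 classes to fit")
    unknown = set(labels) - set(class_labels)
    if unknown:
        raise FitError(f"labels {sorted(unknown)} not in class_labels {class_labels}")
    y = np.array([class_labels.index(l) for l in labels])

    rng = np.random.default_rng(seed)
    # stratified split
    train_idx, test_idx = [], []
    for cls in range(len(class_labels)):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:n_tr])
        test_idx.extend(idx[n_tr:])
    train_idx = np.sort(np.array(train_idx, dtype=int))
    test_idx = np.sort(np.array(test_idx, dtype=int))

    model = SmallCnn(
        layers=default_architecture(images.shape[1:], len(class_labels), seed),
        class_labels=class_labels, seed=seed, input_shape=images.shape[1:],
        train_indices=train_idx, test_indices=test_idx,
    )
    X = images[:, None, :, :]
    # Adam state per trainable parameter
    state = {}
    for li, layer in enumerate(model.trainable()):
        for p in layer.params:
            v = getattr(layer, p)
            state[(li, p)] = (np.zeros_like(v), np.zeros_like(v))
    t = 0
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    for _epoch in range(epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        for start in range(0, order.size, batch_size):
            batch = order[start:start + batch_size]
            logits = model.forward(X[batch])
            probs = _softmax(logits)
            dlogits = probs.copy()
            dlogits[np.arange(batch.size), y[batch]] -= 1.0
            dlogits /= batch.size
            grad = dlogits
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
            t += 1
            for li, layer in enumerate(model.trainable()):
                for p in layer.params:
                    g = getattr(layer, "d" + p)
                    m_t, v_t = state[(li, p)]
                    m_t = beta1 * m_t + (1 - beta1) * g
                    v_t = beta2 * v_t + (1 - beta2) * g * g
                    state[(li, p)] = (m_t, v_t)
                    m_hat = m_t / (1 - beta1**t)
                    v_hat = v_t / (1 - beta2**t)
                    setattr(layer, p, getattr(layer, p) - lr * m_hat / (np.sqrt(v_hat) + adam_eps))
    if test_idx.size:
        preds = model.forward(X[test_idx]).argmax(axis=1)
        model.holdout_accuracy = float((preds == y[test_idx]).mean())
    return model


def classify(image: np.ndarray, model: SmallCnn) -> dict[str, float]:
    """Softmax class probabilities for a single image (resized/padded to fit)."""
    img = np.asarray(image, dtype=float)
    if img.shape != tuple(model.input_shape):
        img = resize(img, model.input_shape, anti_aliasing=False)
    probs = _softmax(model.forward(img[None, None, :, :]))[0]
    return {lab: float(p) for lab, p in zip(model.class_labels, probs)}


def classifier_for_detector(model: SmallCnn) -> Callable[[np.ndarray], dict[str, float]]:
    """Adapt a trained SmallCnn into a DetectorConfig.classifier callable."""
    return lambda crop: classify(crop, model)
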