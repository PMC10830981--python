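"""Layer-wise relevance propagation (epsilon rule) for the small CNN.

The classifier's pre-softmax score for a target class is redistributed
backward through the network layer by layer.  For a linear/convolutional
layer with contributions z_ij = a_i w_ij and preactivation z_j = sum_i z_ij
+ b_j, the epsilon rule sends

    R_i = sum_j  z_ij / (z_j + eps * sign(z_j)) * R_j

to the lower layer.  With eps = 0 and zero biases the total relevance is
conserved exactly across every adjacent layer pair (the sum over i of the
messages into j equals R_j); with eps > 0 a bounded leakage of at most
eps * n_neurons * max|relevance message| / min|z| is traded for numerical
stability.  Max-pooling routes relevance winner-take-all to the argmax of
each window; average-pooling splits it proportionally to the window
activations; ReLU and reshaping pass relevance through unchanged.

Relevance is computed for the pre-softmax score (not the probability),
which is what makes the conservation property hold and makes relevance
scale linearly with the output initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .img2graph import (AvgPool2D, Conv2D, Dense, Flatten, MaxPool2D, ReLU,
                        SmallCnn)


class UnsupportedLayerError(TypeError):
    """The network contains a layer type LRP cannot redistribute through."""


@dataclass
class RelevanceMap:
    """Per-layer relevance arrays, outermost first.

    ``relevances[k]`` is the relevance at the *input* of layer k (so
    ``relevances[0]`` is the pixel-level map and ``relevances[-1]`` the
    output-layer initialization); shapes match the forward activations.
    """

    relevances: list[np.ndarray]
    layer_names: list[str]
    target_class: int
    epsilon: float

    @property
    def input_relevance(self) -> np.ndarray:
        """Pixel relevance reshaped to the image plane."""
        r = self.relevances[0]
        return np.squeeze(r)

    def layer_index(self, layer) -> int:
        if isinstance(layer, int):
            if not -len(self.relevances) <= layer < len(self.relevances):
                raise LookupError(f"no relevance layer {layer}")
            return layer % len(self.relevances)
        try:
            return self.layer_names.index(layer)
        except ValueError:
            raise LookupError(
                f"unknown layer {layer!r}; known: {self.layer_names}") from None


def _stabilized(z: np.ndarray, epsilon: float) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)
    denom = z + epsilon * sign
    # a zero denominator can only carry zero relevance; avoid 0/0
    denom = np.where(denom == 0, 1.0, denom)
    return denom


def lrp_propagate(model: SmallCnn, image: np.ndarray, target_class,
                  epsilon: float = 1e-6) -> RelevanceMap:
    """Propagate the target class's pre-softmax score back to the pixels."""
    if isinstance(target_class, str):
        target_class = model.class_labels.index(target_class)
    img = np.asarray(image, dtype=float)
    x = img[None, None, :, :] if img.ndim == 2 else img
    # forward pass fills every layer's caches
    activations = [x]
    out = x
    for layer in model.layers:
        out = layer.forward(out)
        activations.append(out)
    logits = out[0]
    R = np.zeros_like(out)
    R[0, target_class] = logits[target_class]

    relevances = [R]
    for layer, a_in in zip(reversed(model.layers), reversed(activations[:-1])):
        R = _propagate_layer(layer, a_in, R, epsilon)
        relevances.append(R)
    relevances.reverse()
    names = [type(l).__name__ + f"_{i}" for i, l in enumerate(model.layers)] + ["output"]
    return RelevanceMap(relevances=relevances, layer_names=names,
                        target_class=int(target_class), epsilon=float(epsilon))


def _propagate_layer(layer, a_in: np.ndarray, R: np.ndarray, eps: float) -> np.ndarray:
    if isinstance(layer, Dense):
        z = a_in @ layer.W + layer.b
        s = R / _stabilized(z, eps)
        return a_in * (s @ layer.W.T)
    if isinstance(layer, Conv2D):
        Wmat = layer.W.reshape(layer.W.shape[0], -1)
        cols = layer.cols  # cached by forward: (n, Ho, Wo, C*k*k)
        z = cols @ Wmat.T + layer.b
        s = R.transpose(0, 2, 3, 1) / _stabilized(z, eps)
        contrib = (s @ Wmat) * cols
        return layer._fold(contrib)
    if isinstance(layer, ReLU):
        return R
    if isinstance(layer, Flatten):
        return R.reshape(layer.x_shape)
    if isinstance(layer, MaxPool2D):
        return layer._scatter(R)
    if isinstance(layer, AvgPool2D):
        s_sz = layer.size
        x = layer.x
        n, c, h, w = x.shape
        win_sum = x.reshape(n, c, h // s_sz, s_sz, w // s_sz, s_sz).sum(axis=(3, 5))
        share = R / _stabilized(win_sum, eps)
        share = np.repeat(np.repeat(share, s_sz, axis=2), s_sz, axis=3)
        return x * share
    raise UnsupportedLayerError(
        f"LRP has no rule for layer type {type(layer).__name__}")


# --------------------------------------------------------------------------
# Visualization helpers
# --------------------------------------------------------------------------

def relevance_heatmap(rmap: RelevanceMap, layer=0) -> np.ndarray:
    """2-D heatmap in [0, 1]: |relevance| normalized by its max, channel-summed.

    An all-zero relevance layer yields a flat zero heatmap.
    """
    idx = rmap.layer_index(layer)
    r = np.squeeze(rmap.relevances[idx])
    while r.ndim > 2:
        r = r.sum(axis=0)
    if r.ndim != 2:
        r = np.atleast_2d(r)
    peak = np.abs(r).max()
    return np.abs(r) / peak if peak > 0 else np.zeros_like(r)


def save_heatmap_png(heat: np.ndarray, path, image: np.ndarray | None = None,
                     cmap: str = "hot", alpha: float = 0.6) -> None:
    """Write a heatmap (optionally blended over a grayscale image) as PNG.

    Byte-deterministic for identical inputs.
    """
    rgba = colormaps[cmap](np.clip(heat, 0.0, 1.0))[..., :3]
    if image is not None:
        base = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)[..., None]
        rgba = (1 - alpha) * np.repeat(base, 3, axis=-1) + alpha * rgba
    arr = np.round(np.clip(rgba, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def pixel_density_histogram(data, channel: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over [0, 1] of a heatmap, image, or relevance layer.

    ``data`` may be an array (a channel index selects a plane of a 3-D
    array) or a :class:`RelevanceMap`, in which case the normalized pixel
    heatmap is binned.  Values are clipped into [0, 1] so the counts always
    sum to the pixel count.
    """
    if isinstance(data, RelevanceMap):
        arr = relevance_heatmap(data, 0)
    else:
        arr = np.asarray(data, dtype=float)
    if channel is not None:
        if arr.ndim < 3:
            raise LookupError(f"no channel axis to index with channel={channel}")
        arr = arr[..., channel] if arr.shape[-1] <= 4 else arr[channel]
    edges = np.linspace(0.0, 1.0, 257)
    counts, _ = np.histogram(np.clip(arr, 0.0, 1.0), bins=edges)
    return counts, edges
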