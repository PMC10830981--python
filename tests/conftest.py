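"""Shared fixtures: phantom configs and small network fixtures."""

import numpy as np
import pytest

import mmxai
from mmxai.img2graph import (AvgPool2D, Conv2D, Dense, Flatten, MaxPool2D,
                             ReLU, SmallCnn)


def three_blob_config(seed: int) -> mmxai.PhantomImageConfig:
    """Phantoms with exactly 3 high-contrast, well-separated blobs."""
    return mmxai.PhantomImageConfig(
        n_images=5, height=48, width=48,
        class_labels=("mild dementia",),
        blobs_per_class={"mild dementia": {"count": (3, 3),
                                           "intensity": (0.7, 0.9),
                                           "radius": (4, 6)}},
        background_noise_sd=0.01, min_separation=16, seed=seed)


def count_only_config(seed: int, n_images: int = 400,
                      counts=((0, 0), (1, 2), (3, 4), (5, 6))) -> mmxai.PhantomImageConfig:
    """Phantoms whose four severity classes differ only in blob count."""
    labels = ("non-dementia", "very mild dementia", "mild dementia",
              "moderate dementia")
    blobs = {lab: {"count": c, "intensity": (0.75, 0.75), "radius": (4, 4)}
             for lab, c in zip(labels, counts)}
    return mmxai.PhantomImageConfig(
        n_images=n_images, height=40, width=40, min_separation=9,
        blobs_per_class=blobs, background_noise_sd=0.01, seed=seed)


def positive_cnn(seed: int = 1) -> SmallCnn:
    """A deep zero-bias network with positive weights on 16x16 input.

    Positive weights and positive input give strictly positive
    preactivations, the regime where the epsilon rule at eps=0 conserves
    relevance exactly.
    """
    rng = np.random.default_rng(seed)
    layers = [Conv2D(1, 3, 5, rng), ReLU(), MaxPool2D(2),
              Conv2D(3, 4, 3, rng), ReLU(), AvgPool2D(2),
              Flatten(), Dense(16, 4, rng)]
    for layer in layers:
        if hasattr(layer, "W"):
            layer.W = np.abs(layer.W)
            layer.b = np.zeros_like(layer.b)
    return SmallCnn(layers=layers, input_shape=(16, 16))


@pytest.fixture(scope="session")
def trained_count_cnn():
    """A CNN trained once on count-only phantoms, shared across tests."""
    cfg = count_only_config(seed=3, n_images=200, counts=((0, 0), (1, 1), (3, 4), (5, 6)))
    images, labels, boxes = mmxai.gen_images(cfg)
    model = mmxai.train_classifier(images, labels,
                                   {"epochs": 30, "seed": 3, "learning_rate": 0.01})
    return model, images, labels, boxes
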