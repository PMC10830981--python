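"""Seeded generators for the three study modalities with known ground truth.

Three generators emulate the data sources of a dementia cohort study so every
downstream stage (graph construction, classifier training, the explainers)
can be exercised against planted truth:

* :func:`gen_tabular` — an OASIS-style cross-sectional patient table (age,
  sex, MMSE-like mental state, CDR-like clinical dementia rating, normalized
  whole-brain volume, estimated intracranial volume) with a binary
  demented / non-demented label and configurable per-feature effect sizes.
* :func:`gen_images` — grayscale brain-slice-like phantoms: isotropic
  Gaussian "lesion" blobs truncated at 3 sigma on a noisy background, four
  severity labels distinguished by blob count, and exact bounding boxes.
* :func:`gen_expression` — a genes-by-samples expression matrix where a small
  set of named driver genes feeds a logistic model of the AD / non-AD label;
  the class is the only collider, so the Markov blanket of the class equals
  the driver set by construction.

All generators are pure functions of their config (fixed seed implies
byte-identical output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from PIL import Image

DEMENTED, NONDEMENTED = "demented", "non-demented"
IMAGE_CLASS_LABELS = (
    "mild dementia",
    "moderate dementia",
    "non-dementia",
    "very mild dementia",
)
DEFAULT_DRIVERS = ("CTAGE6", "F8A2", "SAMD7")
CDR_LEVELS = (0.0, 0.5, 1.0, 2.0)

TABULAR_FEATURES = (
    "age",
    "sex",
    "mental_state",
    "clinical_dementia",
    "normalized_brain_volume",
    "intracranial_volume",
)


class ConfigError(ValueError):
    """Invalid generator configuration; message lists offending fields."""


def _require(errors: list[str], ok: bool, msg: str) -> None:
    if not ok:
        errors.append(msg)


# --------------------------------------------------------------------------
# Tabular cohort
# --------------------------------------------------------------------------

def _default_feature_spec() -> dict[str, dict[str, float]]:
    # Baseline (non-demented) distributions; units: years, score points,
    # brain-volume fraction, cm^3.  CDR is a class-conditional categorical
    # over levels (0, 0.5, 1, 2); its base probabilities sit here.
    return {
        "age": {"mean": 72.0, "sd": 9.0},
        "sex": {"p": 0.55},
        "mental_state": {"mean": 27.0, "sd": 2.0, "lo": 0.0, "hi": 30.0},
        "clinical_dementia": {"probs": (0.70, 0.20, 0.08, 0.02)},
        "normalized_brain_volume": {"mean": 0.74, "sd": 0.04, "lo": 0.5, "hi": 0.95},
        "intracranial_volume": {"mean": 1490.0, "sd": 160.0},
    }


def _default_effect_sizes() -> dict[str, float]:
    # Mean shift (demented minus non-demented) per feature.  sex is a shift
    # in the Bernoulli probability; clinical_dementia is an exponential-tilt
    # coefficient on the level value (0 means identical distributions).
    return {
        "age": 4.0,
        "sex": 0.0,
        "mental_state": -5.0,
        "clinical_dementia": 3.0,
        "normalized_brain_volume": -0.04,
        "intracranial_volume": 0.0,
    }


@dataclass
class TabularCohortConfig:
    n_patients: int = 416
    class_balance: float = 0.5
    feature_spec: dict = field(default_factory=_default_feature_spec)
    effect_sizes: dict = field(default_factory=_default_effect_sizes)
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        _require(errors, self.n_patients >= 2, "n_patients must be >= 2")
        _require(errors, 0.0 < self.class_balance < 1.0, "class_balance must be strictly inside (0, 1)")
        spec = self.feature_spec
        for name in TABULAR_FEATURES:
            _require(errors, name in spec, f"feature_spec missing {name!r}")
        if "age" in spec:
            _require(errors, spec["age"].get("sd", 1.0) > 0, "age sd must be > 0")
        if "mental_state" in spec:
            _require(errors, spec["mental_state"].get("sd", 1.0) > 0, "mental_state sd must be > 0")
        if "normalized_brain_volume" in spec:
            _require(errors, spec["normalized_brain_volume"].get("sd", 1.0) > 0,
                     "normalized_brain_volume sd must be > 0")
        if "intracranial_volume" in spec:
            _require(errors, spec["intracranial_volume"].get("sd", 1.0) > 0,
                     "intracranial_volume sd must be > 0")
        if "sex" in spec:
            _require(errors, 0.0 <= spec["sex"].get("p", 0.5) <= 1.0, "sex p must be in [0, 1]")
        if errors:
            raise ConfigError("; ".join(errors))


def gen_tabular(config: TabularCohortConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table with a ``class`` label column.

    Returns ``(table, ground_truth)`` where ``ground_truth`` records the
    per-feature effect sizes actually planted (demented minus non-demented
    expected shift).  Label counts follow ``round(class_balance *
    n_patients)`` exactly; row order is a seeded shuffle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_dem = int(round(config.class_balance * n))
    n_dem = min(max(n_dem, 1), n - 1)
    labels = np.array([DEMENTED] * n_dem + [NONDEMENTED] * (n - n_dem))
    rng.shuffle(labels)
    is_dem = labels == DEMENTED

    spec = config.feature_spec
    eff = config.effect_sizes
    cols: dict[str, np.ndarray] = {}

    def gaussian(name: str) -> np.ndarray:
        s = spec[name]
        x = rng.normal(s["mean"], s["sd"], size=n)
        x = x + np.where(is_dem, eff.get(name, 0.0), 0.0)
        if "lo" in s:
            x = np.clip(x, s["lo"], s["hi"])
        return x

    cols["age"] = np.round(gaussian("age"), 1)
    p_sex = np.clip(spec["sex"]["p"] + np.where(is_dem, eff.get("sex", 0.0), 0.0), 0.0, 1.0)
    cols["sex"] = (rng.random(n) < p_sex).astype(int)
    cols["mental_state"] = np.round(gaussian("mental_state"), 1)
    base_probs = np.asarray(spec["clinical_dementia"]["probs"], dtype=float)
    tilt = eff.get("clinical_dementia", 0.0)
    levels = np.asarray(CDR_LEVELS)
    dem_probs = base_probs * np.exp(tilt * levels)
    dem_probs = dem_probs / dem_probs.sum()
    cdr = np.empty(n)
    u = rng.random(n)
    for i in range(n):
        p = dem_probs if is_dem[i] else base_probs
        cdr[i] = levels[np.searchsorted(np.cumsum(p), u[i])]
    cols["clinical_dementia"] = cdr
    cols["normalized_brain_volume"] = np.round(gaussian("normalized_brain_volume"), 4)
    cols["intracranial_volume"] = np.round(gaussian("intracranial_volume"), 1)

    table = pd.DataFrame(cols)
    table["class"] = labels
    ground_truth = {
        "effect_sizes": dict(eff),
        "n_demented": int(n_dem),
        "n_non_demented": int(n - n_dem),
        "seed": config.seed,
    }
    return table, ground_truth


# --------------------------------------------------------------------------
# Phantom images
# --------------------------------------------------------------------------

def _default_blobs_per_class() -> dict[str, dict]:
    # Severity encoded as lesion-blob count; intensity is peak amplitude in
    # [0, 1]; radius is the 3-sigma truncation radius in pixels.
    return {
        "non-dementia": {"count": (0, 0), "intensity": (0.6, 0.9), "radius": (3, 6)},
        "very mild dementia": {"count": (1, 2), "intensity": (0.6, 0.9), "radius": (3, 6)},
        "mild dementia": {"count": (3, 4), "intensity": (0.6, 0.9), "radius": (3, 6)},
        "moderate dementia": {"count": (5, 6), "intensity": (0.6, 0.9), "radius": (3, 6)},
    }


@dataclass
class PhantomImageConfig:
    n_images: int = 64
    height: int = 32
    width: int = 32
    class_labels: tuple = IMAGE_CLASS_LABELS
    blobs_per_class: dict = field(default_factory=_default_blobs_per_class)
    background_noise_sd: float = 0.02
    min_separation: float = 0.0  # min center distance in px; 0 disables
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        _require(errors, self.n_images >= 1, "n_images must be >= 1")
        _require(errors, self.height >= 16 and self.width >= 16, "height and width must be >= 16")
        _require(errors, self.background_noise_sd >= 0, "background_noise_sd must be >= 0")
        limit = min(self.height, self.width) / 4
        for label in self.class_labels:
            if label not in self.blobs_per_class:
                errors.append(f"blobs_per_class missing {label!r}")
                continue
            s = self.blobs_per_class[label]
            _require(errors, s["radius"][1] < limit,
                     f"{label!r}: blob radius {s['radius'][1]} must be < min(height,width)/4 = {limit}")
            _require(errors, 0.0 <= s["intensity"][0] <= s["intensity"][1] <= 1.0,
                     f"{label!r}: intensities must lie in [0, 1]")
            _require(errors, s["count"][0] >= 0 and s["count"][0] <= s["count"][1],
                     f"{label!r}: bad count range")
        if errors:
            raise ConfigError("; ".join(errors))


def _place_blob(rng, h, w, radius_range, centers, min_sep):
    """Sample an integer blob center and radius with the box in bounds."""
    for _ in range(200):
        radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
        if radius >= min(h, w) // 2:
            continue
        cy = int(rng.integers(radius, h - radius))
        cx = int(rng.integers(radius, w - radius))
        if min_sep > 0 and any((cy - y) ** 2 + (cx - x) ** 2 < min_sep**2 for y, x in centers):
            continue
        return cy, cx, radius
    raise ConfigError("blob geometry infeasible for image size (placement rejection limit hit)")


def gen_images(config: PhantomImageConfig) -> tuple[np.ndarray, list[str], list[list[tuple[int, int, int, int]]]]:
    """Generate phantom images, labels, and per-image ground-truth boxes.

    Each blob is an isotropic Gaussian of peak amplitude A truncated at
    3 sigma (sigma = radius / 3); its ground-truth box is the tight 3-sigma
    bound ``(row_min, col_min, row_max, col_max)``, 0-based half-open.
    Images are float arrays in [0, 1]; see :func:`write_png` for the 8-bit
    on-disk form.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w]
    images = np.zeros((config.n_images, h, w))
    labels: list[str] = []
    boxes: list[list[tuple[int, int, int, int]]] = []
    n_classes = len(config.class_labels)
    for i in range(config.n_images):
        label = config.class_labels[i % n_classes]
        spec = config.blobs_per_class[label]
        count = int(rng.integers(spec["count"][0], spec["count"][1] + 1))
        img = np.zeros((h, w))
        img_boxes = []
        centers: list[tuple[int, int]] = []
        for _ in range(count):
            cy, cx, radius = _place_blob(rng, h, w, spec["radius"], centers, config.min_separation)
            centers.append((cy, cx))
            amp = rng.uniform(spec["intensity"][0], spec["intensity"][1])
            sigma = radius / 3.0
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            blob = amp * np.exp(-d2 / (2 * sigma**2))
            blob[d2 > radius**2] = 0.0
            img += blob
            img_boxes.append((cy - radius, cx - radius, cy + radius + 1, cx + radius + 1))
        if config.background_noise_sd > 0:
            img += rng.normal(0.0, config.background_noise_sd, size=(h, w))
        images[i] = np.clip(img, 0.0, 1.0)
        labels.append(label)
        boxes.append(img_boxes)
    return images, labels, boxes


def write_png(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale PNG (v -> round(255 v))."""
    arr = np.round(np.clip(image, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def read_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to float in [0, 1]."""
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


def write_image_dataset(out_dir: str | Path, images, labels, boxes) -> None:
    """Write PNGs plus a JSON sidecar with labels and ground-truth boxes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, (img, label, img_boxes) in enumerate(zip(images, labels, boxes)):
        name = f"phantom_{i:04d}.png"
        write_png(img, out / name)
        meta.append({"file": name, "label": label, "boxes": [list(map(int, b)) for b in img_boxes]})
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------------
# Gene expression
# --------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    n_genes: int = 200
    n_samples: int = 104
    n_drivers: int = 3
    driver_names: tuple = DEFAULT_DRIVERS
    edge_strength: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        _require(errors, self.n_genes >= 1, "n_genes must be >= 1")
        _require(errors, self.n_samples >= 2, "n_samples must be >= 2")
        _require(errors, 1 <= self.n_drivers <= self.n_genes,
                 "n_drivers must satisfy 1 <= n_drivers <= n_genes")
        _require(errors, self.edge_strength >= 0.0, "edge_strength must be >= 0")
        _require(errors, self.noise_sd > 0.0, "noise_sd must be > 0")
        _require(errors, len(self.driver_names) >= self.n_drivers,
                 "driver_names must provide at least n_drivers labels")
        if errors:
            raise ConfigError("; ".join(errors))


def gen_expression(config: ExpressionSimConfig) -> tuple[pd.DataFrame, np.ndarray, nx.DiGraph]:
    """Generate expression matrix (genes x samples), labels, and planted DAG.

    Each gene g has baseline level mu_g (drawn once per dataset) plus
    Gaussian noise of sd ``noise_sd``.  The class label is Bernoulli with
    log-odds ``edge_strength * sum_d z_d`` over the standardized driver
    values, so driver genes are the parents of the class node and the class
    is the only collider: its Markov blanket is exactly the driver set.
    Labels are the strings ``"AD"`` / ``"non-AD"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p, n = config.n_genes, config.n_samples
    drivers = list(config.driver_names[: config.n_drivers])
    gene_names = [f"GENE{i:05d}" for i in range(p)]
    driver_rows = rng.choice(p, size=config.n_drivers, replace=False)
    for row, name in zip(driver_rows, drivers):
        gene_names[row] = name

    mu = rng.normal(8.0, 2.0, size=p)
    z = rng.standard_normal((p, n))
    values = mu[:, None] + config.noise_sd * z

    logits = config.edge_strength * z[driver_rows, :].sum(axis=0)
    prob_ad = 1.0 / (1.0 + np.exp(-logits))
    labels = np.where(rng.random(n) < prob_ad, "AD", "non-AD")

    matrix = pd.DataFrame(values, index=gene_names,
                          columns=[f"patient_{j:04d}" for j in range(n)])
    dag = nx.DiGraph()
    dag.add_node("class")
    for name in drivers:
        dag.add_edge(name, "class")
    return matrix, labels, dag


def write_expression_tsv(matrix: pd.DataFrame, labels: np.ndarray, path: str | Path) -> None:
    """Write genes-in-rows TSV with a final ``label`` metadata row (AD/non-AD)."""
    out = matrix.copy()
    out.loc["label"] = list(labels)
    out.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a TSV written by :func:`write_expression_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.index:
        raise ValueError("expression TSV has no 'label' metadata row")
    labels = df.loc["label"].to_numpy(dtype=str)
    matrix = df.drop(index="label").astype(float)
    return matrix, labels
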