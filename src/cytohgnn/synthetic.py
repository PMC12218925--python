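"""Deterministic synthetic inputs with the statistical structure the
classifier assumes.

Two generators:

* Gaussian feature clusters — isotropic class-conditional Gaussians whose
  means sit at a controlled mutual distance, expressed in multiples of the
  within-class standard deviation.  Emulates CNN feature tables without a
  backbone pass.
* Toy cell images — ellipse "cytoplasm" with an inner "nucleus", one
  subdirectory per class, where classes differ by nucleus/cytoplasm area
  ratio and stain hue.  Emulates the one-directory-per-class single-cell
  image layout of Pap-smear collections.

Both are bit-reproducible from their seed.  A small 4-point worked
hypergraph instance with hand-computed expectations is provided for
regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidConfigError
from .feature_table import FeatureTable

__all__ = [
    "ClusterSpec",
    "ToyImageSpec",
    "DEFAULT_CLASS_NAMES",
    "gen_feature_clusters",
    "gen_cell_images",
    "make_cell_image_arrays",
    "toy_fixture",
    "ToyHypergraphFixture",
]

#: The five cervical cytology subtypes, in lexicographic order (the order a
#: directory reader produces).
DEFAULT_CLASS_NAMES = (
    "Dyskeratotic",
    "Koilocytotic",
    "Metaplastic",
    "Parabasal",
    "Superficial_intermediate",
)


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian-mixture feature-table specification.

    ``class_mean_separation`` is the mutual distance between class means in
    multiples of ``noise_sd`` (the within-class standard deviation); 0
    collapses all means to one point (pure noise), 8 gives essentially
    separable classes.
    """

    n_classes: int = 5
    n_per_class: int = 100
    dim: int = 64
    class_mean_separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 5:
            raise InvalidConfigError("n_per_class must be >= 5")
        if self.dim < 2:
            raise InvalidConfigError("dim must be >= 2")
        if self.class_mean_separation < 0 or self.noise_sd <= 0:
            raise InvalidConfigError("separation must be >= 0 and noise_sd > 0")
        if not (2 <= self.n_classes <= self.dim):
            raise InvalidConfigError("need 2 <= n_classes <= dim for equidistant means")


def _simplex_means(n_classes: int, dim: int, separation: float) -> np.ndarray:
    """n_classes points in R^dim, pairwise distance exactly ``separation``."""
    # scaled standard-basis simplex: |s e_i - s e_j| = s * sqrt(2)
    scale = separation / np.sqrt(2.0)
    means = np.zeros((n_classes, dim))
    means[np.arange(n_classes), np.arange(n_classes)] = scale
    return means - means.mean(axis=0)


def gen_feature_clusters(spec: ClusterSpec) -> FeatureTable:
    """Draw an isotropic Gaussian-mixture feature table.

    Class means are mutually equidistant at
    ``class_mean_separation * noise_sd``; features are
    ``mean + N(0, noise_sd^2 I)``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    means = _simplex_means(
        spec.n_classes, spec.dim, spec.class_mean_separation * spec.noise_sd
    )
    n = spec.n_classes * spec.n_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    features = means[labels] + rng.normal(0.0, spec.noise_sd, size=(n, spec.dim))
    if spec.n_classes == 5:
        class_names = list(DEFAULT_CLASS_NAMES)
    else:
        class_names = [f"class_{c}" for c in range(spec.n_classes)]
    sample_ids = [f"{class_names[labels[i]]}_{i % spec.n_per_class:04d}" for i in range(n)]
    return FeatureTable(features, labels, sample_ids, class_names)


# ------------------------------------------------------------------ #


@dataclass(frozen=True)
class ToyImageSpec:
    """Toy single-cell image specification.

    Per class: cytoplasm ellipse semi-axes (fractions of the half image),
    nucleus/cytoplasm area ratio, RGB stain hue, and additive texture
    noise.  Nucleus area ratios are strictly increasing across the default
    classes, so the label is recoverable from morphology by construction.
    """

    image_size: int = 64
    n_per_class: int = 20
    nucleus_ratios: Tuple[float, ...] = (0.10, 0.22, 0.34, 0.46, 0.58)
    cytoplasm_axes: Tuple[Tuple[float, float], ...] = (
        (0.90, 0.70), (0.80, 0.80), (0.85, 0.60), (0.70, 0.70), (0.95, 0.55)
    )
    hues: Tuple[Tuple[float, float, float], ...] = (
        (0.85, 0.45, 0.55),
        (0.55, 0.75, 0.50),
        (0.50, 0.55, 0.85),
        (0.80, 0.75, 0.40),
        (0.60, 0.50, 0.80),
    )
    texture_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise InvalidConfigError("image_size must be >= 64")
        if self.n_per_class < 1:
            raise InvalidConfigError("n_per_class must be >= 1")
        n = len(self.nucleus_ratios)
        if not (len(self.cytoplasm_axes) == len(self.hues) == n):
            raise InvalidConfigError("per-class parameter tuples must have equal length")
        if any(not (0 < r < 1) for r in self.nucleus_ratios):
            raise InvalidConfigError("nucleus/cytoplasm area ratios must lie in (0, 1)")

    @property
    def n_classes(self) -> int:
        return len(self.nucleus_ratios)


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _render_cell(rng: np.random.Generator, spec: ToyImageSpec, cls: int) -> np.ndarray:
    s = spec.image_size
    half = s / 2.0
    ax_frac, ay_frac = spec.cytoplasm_axes[cls]
    jitter = rng.uniform(0.92, 1.0, size=2)
    ax = ax_frac * half * jitter[0]
    ay = ay_frac * half * jitter[1]
    cx = half + rng.uniform(-0.03, 0.03) * s
    cy = half + rng.uniform(-0.03, 0.03) * s
    cyto = _ellipse_mask(s, cx, cy, ax, ay)
    # nucleus axes scaled so that area ratio matches the class parameter;
    # same eccentricity as the cytoplasm keeps the nucleus inside it
    ratio = spec.nucleus_ratios[cls]
    nx, ny = ax * np.sqrt(ratio), ay * np.sqrt(ratio)
    nucleus = _ellipse_mask(s, cx, cy, nx, ny)

    hue = np.asarray(spec.hues[cls])
    img = np.full((s, s, 3), 0.95)  # light background
    img[cyto] = hue
    img[nucleus] = hue * 0.35  # darker chromatin
    img += rng.normal(0.0, spec.texture_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_cell_image_arrays(spec: ToyImageSpec):
    """In-memory toy cells: (images uint8 (N,s,s,3), labels, class names)."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_classes == 5:
        class_names = list(DEFAULT_CLASS_NAMES)
    else:
        class_names = [f"class_{c}" for c in range(spec.n_classes)]
    images, labels = [], []
    for cls in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            img = _render_cell(rng, spec, cls)
            images.append(np.round(img * 255.0).astype(np.uint8))
            labels.append(cls)
    return np.stack(images), np.asarray(labels, dtype=np.int64), class_names


def gen_cell_images(spec: ToyImageSpec, root) -> Path:
    """Write the toy images as PNGs, one subdirectory per class.

    Produces the same layout a directory reader expects:
    ``root/<class_name>/<class_name>_<i>.png``.
    """
    root = Path(root)
    images, labels, class_names = make_cell_image_arrays(spec)
    counters = {c: 0 for c in range(spec.n_classes)}
    for img, cls in zip(images, labels):
        cls = int(cls)
        cls_dir = root / class_names[cls]
        cls_dir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(cls_dir / f"{class_names[cls]}_{counters[cls]:04d}.png", img)
        counters[cls] += 1
    return root


# ------------------------------------------------------------------ #


@dataclass(frozen=True)
class ToyHypergraphFixture:
    """The 4-point, k=1 worked instance with hand-computed expectations."""

    points: np.ndarray
    labels: np.ndarray
    expected_H: np.ndarray
    expected_Dv: np.ndarray
    expected_De: np.ndarray
    expected_P: np.ndarray
    k: int = 1


def toy_fixture() -> ToyHypergraphFixture:
    """Four points in two tight pairs far apart; k=1 hyperedges.

    Points (0,0), (0,1), (10,0), (10,1) with labels (0,0,1,1).  Each
    hyperedge pairs a point with its unique nearest neighbour, so H has
    column sums 2, all degrees are 2, and the propagation operator is
    block diagonal: P couples {0,1} and {2,3} internally (each block is
    the 2x2 averaging matrix with entries 1/2) and not across.
    """
    points = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = np.array([0, 0, 1, 1])
    H = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    block = np.full((2, 2), 0.5)
    P = np.block(
        [[block, np.zeros((2, 2))], [np.zeros((2, 2)), block]]
    )
    return ToyHypergraphFixture(
        points=points,
        labels=labels,
        expected_H=H,
        expected_Dv=np.full(4, 2.0),
        expected_De=np.full(4, 2.0),
        expected_P=P,
        k=1,
    )
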