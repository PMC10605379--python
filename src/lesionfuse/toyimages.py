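"""Toy lesion images and a tiny trainable classifier harness.

The generator paints one elliptical "lesion" blob per image on a light
skin-toned background.  Class identity is encoded in simple programmed
features — a distinct base hue, blob eccentricity and border roughness
per class — so a trivial rule (or a small learned model) can recover
the label, which is all the fixtures need to exercise the fusion and
metric machinery end to end.  A configurable fraction of images receive
dark curvilinear strokes mimicking the hair artifacts that plague real
dermoscopy photographs.

``ToyClassifier`` variants train a logistic regression on different
feature subsets (color moments, hue histogram, blob shape), so
different variants make partially uncorrelated errors — the property a
decision-fusion ensemble exploits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import measure
from skimage.color import rgb2hsv
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError

__all__ = [
    "ToyImageSpec",
    "CLASS_STYLES",
    "generate_toy_images",
    "save_toy_images",
    "hue_rule_classify",
    "augment_image",
    "ToyClassifier",
    "train_toy_classifier",
    "FEATURE_VARIANTS",
]

# per-class appearance: (base hue, ellipse axis ratio, border roughness amplitude)
CLASS_STYLES: tuple[tuple[float, float, float], ...] = (
    (0.95, 0.55, 0.06),  # reddish, elongated, mildly rough
    (0.10, 0.95, 0.02),  # tan, round, smooth
    (0.55, 0.75, 0.12),  # blue-grey, oval, rough border
    (0.30, 0.85, 0.20),  # olive, near-round, very rough border
)


@dataclass(frozen=True)
class ToyImageSpec:
    """Parameters of one toy image batch."""

    catalog: ClassCatalog = field(default_factory=ClassCatalog)
    per_class: int = 25
    size: int = 48
    artifact_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class <= 0:
            raise StructuralError("per-class image count must be positive")
        if self.size <= 0:
            raise StructuralError("image size must be positive")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise StructuralError("artifact rate must be in [0, 1]")


def _blob_mask(size: int, hue_style: tuple[float, float, float], rng: np.random.Generator) -> np.ndarray:
    _, axis_ratio, rough = hue_style
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2 + rng.uniform(-0.06, 0.06) * size
    cx = size / 2 + rng.uniform(-0.06, 0.06) * size
    angle = rng.uniform(0, np.pi)
    dy, dx = (yy - cy) / size, (xx - cx) / size
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    base_r = rng.uniform(0.26, 0.33)
    theta = np.arctan2(v, u * axis_ratio)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = 1.0 + rough * np.sin(5 * theta + phase) + 0.5 * rough * np.sin(9 * theta - phase)
    radial = np.sqrt((u / axis_ratio) ** 2 + v**2)
    return radial <= base_r * wobble


def _hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = np.select(
        [(i == k)[..., None] for k in range(6)],
        [
            np.stack([v, t, p], -1),
            np.stack([q, v, p], -1),
            np.stack([p, v, t], -1),
            np.stack([p, q, v], -1),
            np.stack([t, p, v], -1),
            np.stack([v, p, q], -1),
        ],
    )
    return rgb


def _draw_strokes(img: np.ndarray, rng: np.random.Generator) -> None:
    """Overlay 2-4 dark random-walk strokes in place (hair-like artifacts)."""
    size = img.shape[0]
    for _ in range(rng.integers(2, 5)):
        y, x = rng.uniform(0, size, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(int(size * 1.5)):
            heading += rng.normal(0, 0.25)
            y += np.sin(heading)
            x += np.cos(heading)
            iy, ix = int(y) % size, int(x) % size
            img[iy, ix] = (0.08, 0.07, 0.06)


def generate_toy_images(spec: ToyImageSpec) -> tuple[list[np.ndarray], list[str]]:
    """Deterministically render the batch; returns (images, labels).

    Images are (size, size, 3) uint8 arrays; labels follow catalog
    order, ``per_class`` images per class.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    for ci, cls in enumerate(spec.catalog):
        style = CLASS_STYLES[ci % len(CLASS_STYLES)]
        for _ in range(spec.per_class):
            img = np.empty((spec.size, spec.size, 3))
            img[:] = (0.91, 0.82, 0.74)  # light skin tone
            img += rng.normal(0, 0.015, size=img.shape)
            mask = _blob_mask(spec.size, style, rng)
            hue = (style[0] + rng.normal(0, 0.012)) % 1.0
            h = np.full(mask.sum(), hue) + rng.normal(0, 0.008, mask.sum())
            s = np.clip(rng.normal(0.62, 0.05, mask.sum()), 0.4, 0.85)
            v = np.clip(rng.normal(0.52, 0.06, mask.sum()), 0.3, 0.75)
            img[mask] = _hsv_to_rgb(h % 1.0, s, v)
            if rng.random() < spec.artifact_rate:
                _draw_strokes(img, rng)
            images.append((np.clip(img, 0, 1) * 255).astype(np.uint8))
            labels.append(cls)
    return images, labels


def save_toy_images(images: Sequence[np.ndarray], labels: Sequence[str], out_dir: str) -> list[str]:
    """Write images as PNGs into class-named subdirectories; returns paths."""
    paths = []
    counters: dict[str, int] = {}
    for img, label in zip(images, labels):
        sub = os.path.join(out_dir, label)
        os.makedirs(sub, exist_ok=True)
        n = counters.get(label, 0)
        counters[label] = n + 1
        path = os.path.join(sub, f"{label}_{n:04d}.png")
        Image.fromarray(img).save(path)
        paths.append(path)
    return paths


def _blob_pixels(hsv: np.ndarray) -> np.ndarray:
    """Boolean mask of lesion pixels: saturated and darker than background."""
    return (hsv[..., 1] > 0.3) & (hsv[..., 2] < 0.8)


def hue_rule_classify(
    image: np.ndarray,
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> str:
    """Nearest-prototype rule on the blob's circular mean hue.

    A deliberately trivial classifier used to check that class identity
    really is recoverable from the programmed appearance.
    """
    cat = as_catalog(catalog)
    hsv = rgb2hsv(np.asarray(image, dtype=float) / 255.0)
    mask = _blob_pixels(hsv)
    if not mask.any():
        return cat.labels[0]
    hues = hsv[..., 0][mask]
    mean_angle = np.angle(np.exp(2j * np.pi * hues).mean()) / (2 * np.pi) % 1.0
    dists = []
    for ci in range(len(cat)):
        proto = CLASS_STYLES[ci % len(CLASS_STYLES)][0]
        d = abs(mean_angle - proto)
        dists.append(min(d, 1 - d))
    return cat.labels[int(np.argmin(dists))]


def augment_image(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random rotation (multiple of 90 degrees) and/or flip."""
    out = np.rot90(image, k=int(rng.integers(0, 4)))
    if rng.random() < 0.5:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# tiny trainable classifier harness
# ---------------------------------------------------------------------------

FEATURE_VARIANTS = ("color", "histogram", "shape")


def _features(image: np.ndarray, variant: str) -> np.ndarray:
    rgb = np.asarray(image, dtype=float) / 255.0
    hsv = rgb2hsv(rgb)
    mask = _blob_pixels(hsv)
    if not mask.any():
        mask = np.ones(hsv.shape[:2], dtype=bool)
    if variant == "color":
        hues = hsv[..., 0][mask]
        circ = np.exp(2j * np.pi * hues).mean()
        return np.array(
            [
                rgb[..., 0][mask].mean(),
                rgb[..., 1][mask].mean(),
                rgb[..., 2][mask].mean(),
                circ.real,
                circ.imag,
                hsv[..., 1][mask].mean(),
                hsv[..., 2][mask].mean(),
            ]
        )
    if variant == "histogram":
        hist, _ = np.histogram(hsv[..., 0][mask], bins=12, range=(0, 1))
        return hist / max(mask.sum(), 1)
    if variant == "shape":
        labelled = measure.label(mask)
        regions = measure.regionprops(labelled)
        region = max(regions, key=lambda r: r.area)
        area_frac = region.area / mask.size
        perim = region.perimeter or 1.0
        compactness = 4 * np.pi * region.area / perim**2
        hues = hsv[..., 0][mask]
        circ = np.exp(2j * np.pi * hues).mean()
        return np.array(
            [
                area_frac,
                region.eccentricity,
                compactness,
                region.solidity,
                circ.real,
                circ.imag,
            ]
        )
    raise StructuralError(f"unknown feature variant {variant!r}; choose from {FEATURE_VARIANTS}")


@dataclass
class ToyClassifier:
    """A trained scorer mapping an image to a soft score row.

    ``classes_`` lists the classes the scorer was trained on (for
    pairwise branches that is just the two pair members); scores align
    with that order and sum to one.
    """

    variant: str
    classes_: tuple[str, ...]
    _model: Pipeline

    def predict_scores(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = np.vstack([_features(img, self.variant) for img in images])
        return self._model.predict_proba(feats)

    def predict_labels(self, images: Sequence[np.ndarray]) -> list[str]:
        scores = self.predict_scores(images)
        return [self.classes_[i] for i in scores.argmax(axis=1)]


def train_toy_classifier(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    variant: str = "color",
    seed: int = 0,
) -> ToyClassifier:
    """Fit a logistic regression on one feature variant.

    Different variants see different feature subsets, so their error
    sets on a batch are partially uncorrelated — the raw material for a
    useful ensemble.  Training is deterministic for fixed data and seed
    and takes well under a second at fixture scale.
    """
    if variant not in FEATURE_VARIANTS:
        raise StructuralError(f"unknown feature variant {variant!r}; choose from {FEATURE_VARIANTS}")
    classes = tuple(dict.fromkeys(labels))
    if len(classes) < 2:
        raise StructuralError("training requires at least two classes")
    feats = np.vstack([_features(img, variant) for img in images])
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(max_iter=1000, random_state=seed)),
        ]
    )
    model.fit(feats, list(labels))
    return ToyClassifier(variant, tuple(model.classes_), model)
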