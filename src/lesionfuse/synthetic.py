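"""Simulated base-classifier outputs with a prescribed confusion structure.

A :class:`ClassifierProfile` specifies, per true class, the probability
with which an emulated classifier predicts each class (a row-stochastic
target confusion), plus a sharpness controlling how peaked its softmax-like
score rows are.  Sampling is two-stage: the predicted class is drawn from
the profile row of the sample's true class, then a soft score row is drawn
from a Dirichlet concentrated on that predicted class, so the hardened
argmax always equals the drawn class and the empirical confusion of a
large sample converges to the target.

Pairwise binary branches are derived from the same profile by
conditioning each row on the branch's two classes, so one generator
grounds both the direct-fusion and the one-vs-one ensemble modes.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError

__all__ = [
    "ClassifierProfile",
    "sample_labels",
    "simulate_predictions",
    "simulate_prediction_table",
    "simulate_branch_decisions",
    "simulate_binary_table",
    "complementary_profiles",
]

#: Default Dirichlet concentration on the winning class of a soft row.
DEFAULT_SHARPNESS = 12.0


@dataclass(frozen=True)
class ClassifierProfile:
    """Target confusion and score sharpness of one emulated base classifier.

    Parameters
    ----------
    catalog
        Class catalog; fixes row/column order of the confusion target.
    confusion
        K x K row-stochastic matrix; entry (t, p) is the probability
        that a sample of true class t is predicted as class p.
    sharpness
        Dirichlet concentration placed on the drawn class when sampling
        a soft score row; larger means more confident rows.
    seed
        Default seed for this profile's own random stream.
    """

    catalog: ClassCatalog
    confusion: np.ndarray
    sharpness: float = DEFAULT_SHARPNESS
    seed: int = 0

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        k = len(self.catalog)
        if conf.shape != (k, k):
            raise StructuralError(f"profile confusion must be {k}x{k}, got {conf.shape}")
        if np.any(conf < 0):
            raise StructuralError("profile confusion entries must be nonnegative")
        if np.any(np.abs(conf.sum(axis=1) - 1.0) > 1e-9):
            raise StructuralError("profile confusion rows must sum to 1")
        if self.sharpness <= 0:
            raise StructuralError(f"sharpness must be positive, got {self.sharpness}")
        object.__setattr__(self, "confusion", conf)

    def row(self, label: str) -> np.ndarray:
        return self.confusion[self.catalog.index(label)]


def sample_labels(
    catalog: ClassCatalog | Sequence[str],
    n_per_class: int | Mapping[str, int],
    seed: int,
) -> list[str]:
    """A shuffled label sequence with the requested per-class counts."""
    cat = as_catalog(catalog)
    counts = (
        {c: int(n_per_class) for c in cat}
        if isinstance(n_per_class, int)
        else dict(n_per_class)
    )
    labels = [c for c in cat for _ in range(counts[c])]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return labels


def simulate_predictions(
    profile: ClassifierProfile,
    true_labels: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Soft score rows for each sample under the profile's confusion target.

    Returns an (n, K) frame of rows summing to one whose per-row argmax
    follows the profile's confusion distribution conditioned on the
    sample's true class.
    """
    rng = np.random.default_rng(profile.seed) if rng is None else rng
    cat = profile.catalog
    k = len(cat)
    true_idx = np.array([cat.index(t) for t in true_labels])
    n = len(true_idx)
    # stage 1: drawn predicted class per sample
    u = rng.random(n)
    cum = np.cumsum(profile.confusion, axis=1)
    pred_idx = np.minimum((u[:, None] > cum[true_idx]).sum(axis=1), k - 1)
    # stage 2: Dirichlet score row concentrated on the drawn class
    alphas = np.ones((n, k))
    alphas[np.arange(n), pred_idx] = profile.sharpness
    gams = rng.standard_gamma(alphas)
    rows = gams / gams.sum(axis=1, keepdims=True)
    # the Dirichlet mode can stray off the drawn class; swap so the
    # hardened argmax always matches the drawn class
    arg = rows.argmax(axis=1)
    off = np.flatnonzero(arg != pred_idx)
    rows[off, arg[off]], rows[off, pred_idx[off]] = (
        rows[off, pred_idx[off]],
        rows[off, arg[off]],
    )
    return pd.DataFrame(rows, columns=list(cat.labels))


def simulate_prediction_table(
    profiles: Mapping[str, ClassifierProfile],
    true_labels: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Joint score table for several emulated models on one sample set.

    Columns: ``sample_id``, ``true_label``, then one ``<model>:<class>``
    column per model and class.
    """
    if not profiles:
        raise StructuralError("at least one classifier profile is required")
    catalogs = {p.catalog for p in profiles.values()}
    if len(catalogs) > 1:
        raise StructuralError("all profiles must share one catalog")
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:05d}" for i in range(len(true_labels))],
            "true_label": list(true_labels),
        }
    )
    for m, (model_id, profile) in enumerate(profiles.items()):
        rng = np.random.default_rng([seed, m])
        rows = simulate_predictions(profile, true_labels, rng=rng)
        for c in profile.catalog:
            table[f"{model_id}:{c}"] = rows[c].to_numpy()
    return table


def simulate_branch_decisions(
    profile: ClassifierProfile,
    pair: tuple[str, str],
    true_labels: Sequence[str],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Soft two-sided decisions of one pairwise branch, shape (n, 2).

    The branch's probability of siding with class a is the profile row
    of the sample's true class conditioned on {a, b}; the soft score of
    the chosen side is drawn in (0.5, 1], so hardening recovers the
    drawn side.
    """
    rng = np.random.default_rng(profile.seed) if rng is None else rng
    cat = profile.catalog
    a, b = cat.canonical_pair(*pair)
    ia, ib = cat.index(a), cat.index(b)
    true_idx = np.array([cat.index(t) for t in true_labels])
    mass_a = profile.confusion[true_idx, ia]
    mass_b = profile.confusion[true_idx, ib]
    denom = mass_a + mass_b
    p_a = np.where(denom > 0, mass_a / np.where(denom > 0, denom, 1.0), 0.5)
    pick_a = rng.random(len(true_idx)) < p_a
    conf = 0.5 + 0.5 * rng.beta(profile.sharpness, 1.0, size=len(true_idx))
    score_a = np.where(pick_a, conf, 1.0 - conf)
    return np.column_stack([score_a, 1.0 - score_a])


def simulate_binary_table(
    profiles: Mapping[str, ClassifierProfile],
    true_labels: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Joint pairwise-branch decision table for several emulated models.

    Columns: ``sample_id``, ``true_label``, then
    ``<model>:<a>_<b>:<class>`` for each model, branch pair and pair
    member — 2 x C(K, 2) score columns per model.
    """
    if not profiles:
        raise StructuralError("at least one classifier profile is required")
    catalogs = {p.catalog for p in profiles.values()}
    if len(catalogs) > 1:
        raise StructuralError("all profiles must share one catalog")
    cat = next(iter(catalogs))
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:05d}" for i in range(len(true_labels))],
            "true_label": list(true_labels),
        }
    )
    for m, (model_id, profile) in enumerate(profiles.items()):
        for j, pair in enumerate(cat.pairs()):
            rng = np.random.default_rng([seed, m, j])
            scores = simulate_branch_decisions(profile, pair, true_labels, rng=rng)
            key = "_".join(pair)
            table[f"{model_id}:{key}:{pair[0]}"] = scores[:, 0]
            table[f"{model_id}:{key}:{pair[1]}"] = scores[:, 1]
    return table


def complementary_profiles(
    catalog: ClassCatalog | Sequence[str] | None = None,
    weak_accuracy: float = 0.70,
    strong_accuracy: float = 0.94,
    sharpness: float = DEFAULT_SHARPNESS,
    seed: int = 0,
) -> dict[str, ClassifierProfile]:
    """Three emulated classifiers with disjoint weak classes.

    Classifier m is weak (per-class accuracy ``weak_accuracy``) on the
    m-th catalog class only and strong everywhere else; its missed mass
    spreads evenly over the other classes.  Because no class is weak
    for more than one classifier, a weighted ensemble can outvote each
    individual mistake — the designed scenario in which decision fusion
    beats every base model.
    """
    cat = as_catalog(catalog)
    k = len(cat)
    if k < 2:
        raise StructuralError("complementary profiles need at least two classes")
    profiles: dict[str, ClassifierProfile] = {}
    for m in range(3):
        weak_class = m % k
        conf = np.full((k, k), (1.0 - strong_accuracy) / (k - 1))
        np.fill_diagonal(conf, strong_accuracy)
        conf[weak_class] = (1.0 - weak_accuracy) / (k - 1)
        conf[weak_class, weak_class] = weak_accuracy
        profiles[f"clf{m + 1}"] = ClassifierProfile(
            cat, conf, sharpness=sharpness, seed=seed + m
        )
    return profiles
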