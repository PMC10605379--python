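"""End-to-end experiment drivers.

Two self-contained studies exercise the full stack without external data:

* :func:`run_complementary_experiment` — three *simulated* base
  classifiers with disjoint weak classes are fused by both ensemble
  rules; because no class is weak for more than one classifier, a
  weighted ensemble can outvote every individual mistake, so fused
  accuracy should reach or beat the best single model.

* :func:`run_toy_image_experiment` — toy images are generated, split
  75/15/10, three classifier variants (plus their 3 x C(K,2) pairwise
  binary branches) are *trained*, fusion weights are estimated on the
  validation split, and both ensembles are evaluated on the test split.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog, as_catalog
from .dataset import ImageRecord, SplitSpec, pair_subsets, split_records
from .metrics import build_confusion, mean_accuracy, per_class_f1
from .synthetic import (
    complementary_profiles,
    sample_labels,
    simulate_binary_table,
    simulate_prediction_table,
)
from .tables import (
    estimate_model1_weights,
    estimate_model2_weights,
    evaluate_decisions,
    fuse_model1_table,
    fuse_model2_table,
    model_ids_from_table,
)
from .toyimages import ToyImageSpec, generate_toy_images, train_toy_classifier

__all__ = ["run_complementary_experiment", "run_toy_image_experiment"]


def individual_accuracies(
    table: pd.DataFrame, catalog: ClassCatalog | Sequence[str] | None = None
) -> dict[str, float]:
    """Hardened-argmax accuracy of each base model in a direct score table."""
    cat = as_catalog(catalog)
    truths = list(table["true_label"])
    out = {}
    for m in model_ids_from_table(table):
        block = table[[f"{m}:{c}" for c in cat]].to_numpy()
        preds = [cat.labels[i] for i in block.argmax(axis=1)]
        out[m] = mean_accuracy(build_confusion(truths, preds, cat))
    return out


def run_complementary_experiment(
    seed: int = 0,
    n_test_per_class: int = 500,
    n_validation_per_class: int = 250,
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> dict:
    """Fuse three complementary-error simulated classifiers both ways.

    Weights for the direct ensemble are per-class F1 estimated on the
    validation split; branch weights for the one-vs-one ensemble come
    from the same split's pairwise decisions.  Returns individual and
    fused test accuracies plus per-class F1 of both ensembles.
    """
    cat = as_catalog(catalog)
    profiles = complementary_profiles(cat, seed=seed)
    val_labels = sample_labels(cat, n_validation_per_class, seed=seed * 2 + 1)
    test_labels = sample_labels(cat, n_test_per_class, seed=seed * 2 + 2)

    val_direct = simulate_prediction_table(profiles, val_labels, seed=seed * 2 + 1)
    test_direct = simulate_prediction_table(profiles, test_labels, seed=seed * 2 + 2)
    val_binary = simulate_binary_table(profiles, val_labels, seed=seed * 2 + 1)
    test_binary = simulate_binary_table(profiles, test_labels, seed=seed * 2 + 2)

    W = estimate_model1_weights(val_direct, cat)
    dec1 = fuse_model1_table(test_direct, W)
    cm1, report1 = evaluate_decisions(dec1, cat)

    bw = estimate_model2_weights(val_binary, cat)
    dec2 = fuse_model2_table(test_binary, bw, cat)
    cm2, report2 = evaluate_decisions(dec2, cat)

    individual = individual_accuracies(test_direct, cat)
    return {
        "individual_accuracy": individual,
        "max_individual_accuracy": max(individual.values()),
        "model1": {"accuracy": report1["mean_accuracy"], "per_class_f1": per_class_f1(cm1),
                   "confusion": cm1, "weights": W},
        "model2": {"accuracy": report2["mean_accuracy"], "per_class_f1": per_class_f1(cm2),
                   "confusion": cm2, "branch_weights": bw},
        "n_test": len(test_labels),
    }


def _scores_in_catalog_order(clf, images, catalog: ClassCatalog) -> np.ndarray:
    """Reorder a trained scorer's probability columns into catalog order."""
    raw = clf.predict_scores(images)
    order = [clf.classes_.index(c) for c in catalog if c in clf.classes_]
    return raw[:, order]


def run_toy_image_experiment(
    seed: int = 0,
    per_class: int = 40,
    size: int = 40,
    artifact_rate: float = 0.1,
    variants: Sequence[str] = ("color", "histogram", "shape"),
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> dict:
    """Train-and-fuse pipeline on generated toy images.

    Generates labelled images, splits them 75/15/10 (stratified),
    trains one multi-class classifier per feature variant plus every
    pairwise binary branch, estimates fusion weights on the validation
    split, fuses the test split with both ensemble rules, and returns
    the confusion matrices and metric reports.
    """
    cat = as_catalog(catalog)
    spec = ToyImageSpec(cat, per_class=per_class, size=size,
                        artifact_rate=artifact_rate, seed=seed)
    images, labels = generate_toy_images(spec)
    records = [ImageRecord(f"img{i:04d}", f"L{i:04d}", lab) for i, lab in enumerate(labels)]
    split = split_records(records, SplitSpec(seed=seed))
    idx = {p: [i for i, r in enumerate(split) if r.partition == p]
           for p in ("train", "validation", "test")}

    def subset(part):
        return [images[i] for i in idx[part]], [labels[i] for i in idx[part]]

    train_imgs, train_labs = subset("train")
    val_imgs, val_labs = subset("validation")
    test_imgs, test_labs = subset("test")
    train_records = [split[i] for i in idx["train"]]

    def make_table(imgs, labs, columns):
        table = pd.DataFrame({
            "sample_id": [f"s{i:04d}" for i in range(len(imgs))],
            "true_label": labs,
        })
        for name, values in columns:
            table[name] = values
        return table

    # multi-class variants -> direct score tables
    direct_cols_val, direct_cols_test = [], []
    for v, variant in enumerate(variants):
        clf = train_toy_classifier(train_imgs, train_labs, variant=variant, seed=seed + v)
        for imgs, cols in ((val_imgs, direct_cols_val), (test_imgs, direct_cols_test)):
            scores = _scores_in_catalog_order(clf, imgs, cat)
            for ci, c in enumerate(cat):
                cols.append((f"{variant}:{c}", scores[:, ci]))
    val_direct = make_table(val_imgs, val_labs, direct_cols_val)
    test_direct = make_table(test_imgs, test_labs, direct_cols_test)

    # pairwise binary branches (len(variants) x C(K,2) binary models)
    pair_records = pair_subsets(train_records, cat)
    n_binary_models = 0
    binary_cols_val, binary_cols_test = [], []
    for v, variant in enumerate(variants):
        for pair, recs in pair_records.items():
            sub_idx = [int(r.image_id[3:]) for r in recs]
            clf = train_toy_classifier(
                [images[i] for i in sub_idx],
                [labels[i] for i in sub_idx],
                variant=variant,
                seed=seed + v,
            )
            n_binary_models += 1
            key = "_".join(pair)
            for imgs, cols in ((val_imgs, binary_cols_val), (test_imgs, binary_cols_test)):
                raw = clf.predict_scores(imgs)
                for member in pair:
                    col = raw[:, clf.classes_.index(member)]
                    cols.append((f"{variant}:{key}:{member}", col))
    val_binary = make_table(val_imgs, val_labs, binary_cols_val)
    test_binary = make_table(test_imgs, test_labs, binary_cols_test)

    W = estimate_model1_weights(val_direct, cat, model_ids=list(variants))
    dec1 = fuse_model1_table(test_direct, W)
    cm1, report1 = evaluate_decisions(dec1, cat)

    bw = estimate_model2_weights(val_binary, cat, model_ids=list(variants))
    dec2 = fuse_model2_table(test_binary, bw, cat)
    cm2, report2 = evaluate_decisions(dec2, cat)

    return {
        "split_sizes": {p: len(idx[p]) for p in idx},
        "n_binary_models": n_binary_models,
        "individual_accuracy": individual_accuracies(test_direct, cat),
        "model1": {"accuracy": report1["mean_accuracy"], "per_class_f1": per_class_f1(cm1),
                   "confusion": cm1, "weights": W, "decisions": dec1},
        "model2": {"accuracy": report2["mean_accuracy"], "per_class_f1": per_class_f1(cm2),
                   "confusion": cm2, "branch_weights": bw, "decisions": dec2},
        "n_test": len(test_labs),
    }
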