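"""CSV score-table workflows: parse, fuse sample-by-sample, evaluate.

Two table layouts are understood, both with leading ``sample_id`` and
``true_label`` columns:

* direct score tables — one ``<model>:<class>`` column per model and
  class (Ensemble Model 1 inputs);
* pairwise decision tables — one ``<model>:<a>_<b>:<class>`` column per
  model, branch pair and pair member (Ensemble Model 2 inputs).

Output CSVs may carry ``#``-prefixed provenance header lines (seed,
config hash); readers skip them.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError
from .fusion import (
    BinaryDecision,
    Branch,
    BinaryBranchSet,
    PredictionMatrix,
    WeightMatrix,
    estimate_binary_weights,
    estimate_weights_from_confusion,
    fuse_model1,
    fuse_model2,
    harden,
)
from .metrics import ConfusionMatrix, build_confusion, mean_accuracy, per_class_f1

__all__ = [
    "read_table",
    "write_table",
    "model_ids_from_table",
    "fuse_model1_table",
    "fuse_model2_table",
    "estimate_model1_weights",
    "estimate_model2_weights",
    "evaluate_decisions",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_branch_weights",
    "write_branch_weights",
    "read_confusion",
    "write_confusion",
]


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("sample_id", "true_label"):
        if col not in df.columns:
            raise StructuralError(f"score table is missing required column {col!r}")
    return df


def write_table(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def model_ids_from_table(df: pd.DataFrame) -> list[str]:
    """Model ids appearing in ``model:...`` score columns, in column order."""
    ids: list[str] = []
    for col in df.columns:
        if ":" in col:
            mid = col.split(":", 1)[0]
            if mid not in ids:
                ids.append(mid)
    if not ids:
        raise StructuralError("no '<model>:<class>' score columns found")
    return ids


def _direct_score_block(
    df: pd.DataFrame, catalog: ClassCatalog, model_ids: Sequence[str]
) -> np.ndarray:
    """Scores as an (n_samples, n_models, K) array, validating columns."""
    cols = []
    for m in model_ids:
        for c in catalog:
            col = f"{m}:{c}"
            if col not in df.columns:
                raise StructuralError(f"score table is missing column {col!r}")
            cols.append(col)
    block = df[cols].to_numpy(dtype=float)
    return block.reshape(len(df), len(model_ids), len(catalog))


def fuse_model1_table(
    table: pd.DataFrame,
    weights: WeightMatrix,
    mode: str = "soft",
) -> pd.DataFrame:
    """Run direct weighted fusion on every sample of a score table.

    Returns a frame with ``sample_id``, ``true_label``, ``predicted``,
    ``tie`` and one fused ``score:<class>`` column per class.
    """
    catalog = weights.catalog
    block = _direct_score_block(table, catalog, weights.model_ids)
    out_rows = []
    for i in range(len(table)):
        P = PredictionMatrix(catalog, weights.model_ids, block[i])
        res = fuse_model1(P, weights, mode=mode)
        out_rows.append((res.predicted, res.tie, *res.scores.as_array()))
    out = pd.DataFrame(
        out_rows, columns=["predicted", "tie", *[f"score:{c}" for c in catalog]]
    )
    out.insert(0, "true_label", table["true_label"].to_numpy())
    out.insert(0, "sample_id", table["sample_id"].to_numpy())
    return out


def _branch_columns(
    df: pd.DataFrame, catalog: ClassCatalog, model_ids: Sequence[str]
) -> dict[tuple[str, tuple[str, str]], tuple[str, str]]:
    cols = {}
    for m in model_ids:
        for pair in catalog.pairs():
            key = "_".join(pair)
            ca, cb = f"{m}:{key}:{pair[0]}", f"{m}:{key}:{pair[1]}"
            if ca not in df.columns or cb not in df.columns:
                raise StructuralError(
                    f"pairwise table is missing columns {ca!r}/{cb!r}"
                )
            cols[(m, pair)] = (ca, cb)
    return cols


def fuse_model2_table(
    table: pd.DataFrame,
    branch_weights: Mapping[str, Mapping[tuple[str, str], tuple[float, float]]],
    catalog: ClassCatalog | Sequence[str] | None = None,
    mode: str = "soft",
) -> pd.DataFrame:
    """Run one-vs-one decomposition fusion on every sample of a pairwise table.

    ``branch_weights`` maps model id -> pair -> (weight_a, weight_b).
    """
    cat = as_catalog(catalog)
    model_ids = list(branch_weights)
    colmap = _branch_columns(table, cat, model_ids)
    out_rows = []
    for i in range(len(table)):
        sets = []
        for m in model_ids:
            branches = {}
            for pair in cat.pairs():
                ca, cb = colmap[(m, pair)]
                dec = BinaryDecision(pair, float(table[ca].iat[i]), float(table[cb].iat[i]))
                wa, wb = branch_weights[m][pair]
                branches[pair] = Branch(dec, wa, wb)
            sets.append(BinaryBranchSet(cat, branches, model_id=m))
        res = fuse_model2(sets, mode=mode)
        out_rows.append((res.predicted, res.tie, *res.scores.as_array()))
    out = pd.DataFrame(
        out_rows, columns=["predicted", "tie", *[f"score:{c}" for c in cat]]
    )
    out.insert(0, "true_label", table["true_label"].to_numpy())
    out.insert(0, "sample_id", table["sample_id"].to_numpy())
    return out


def estimate_model1_weights(
    validation_table: pd.DataFrame,
    catalog: ClassCatalog | Sequence[str] | None = None,
    model_ids: Sequence[str] | None = None,
    policy: str = "f1",
) -> WeightMatrix:
    """Per-(model, class) fusion weights from a labelled validation table.

    Each model's scores are hardened to predictions, tallied into its
    own validation confusion matrix, and converted to per-class F1
    (default policy).  ``'unit'`` returns all-ones weights.
    """
    cat = as_catalog(catalog)
    ids = model_ids_from_table(validation_table) if model_ids is None else list(model_ids)
    if policy == "unit":
        return WeightMatrix.unit(ids, cat)
    if policy != "f1":
        raise StructuralError(f"unknown weight policy {policy!r} for direct fusion")
    block = _direct_score_block(validation_table, cat, ids)
    truths = list(validation_table["true_label"])
    entries = {}
    for mi, m in enumerate(ids):
        preds = [cat.labels[int(np.argmax(harden(block[i, mi], cat)))] for i in range(len(truths))]
        cm = build_confusion(truths, preds, cat)
        entries[m] = estimate_weights_from_confusion(cm)
    return WeightMatrix.from_dict(entries, cat)


def estimate_model2_weights(
    validation_table: pd.DataFrame,
    catalog: ClassCatalog | Sequence[str] | None = None,
    model_ids: Sequence[str] | None = None,
    policy: str = "f1",
) -> dict[str, dict[tuple[str, str], tuple[float, float]]]:
    """Two-sided branch weights per model from a labelled pairwise table.

    Only validation samples whose true class belongs to a branch's pair
    contribute to that branch's 2x2 confusion matrix.
    """
    cat = as_catalog(catalog)
    ids = model_ids_from_table(validation_table) if model_ids is None else list(model_ids)
    colmap = _branch_columns(validation_table, cat, ids)
    truths = list(validation_table["true_label"])
    out: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
    for m in ids:
        decisions: dict[tuple[str, str], list[tuple[BinaryDecision, str]]] = {}
        for pair in cat.pairs():
            ca, cb = colmap[(m, pair)]
            labelled = [
                (BinaryDecision(pair, float(a), float(b)), t)
                for a, b, t in zip(validation_table[ca], validation_table[cb], truths)
                if t in pair
            ]
            decisions[pair] = labelled
        out[m] = estimate_binary_weights(decisions, cat, policy=policy)
    return out


def evaluate_decisions(
    decisions: pd.DataFrame,
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> tuple[ConfusionMatrix, dict]:
    """Confusion matrix plus a metric report from a fused-decision frame."""
    cat = as_catalog(catalog)
    cm = build_confusion(list(decisions["true_label"]), list(decisions["predicted"]), cat)
    report = {
        "n": cm.total,
        "mean_accuracy": mean_accuracy(cm),
        "per_class_f1": per_class_f1(cm),
    }
    return cm, report


# ---------------------------------------------------------------------------
# weight / confusion matrix CSV round-trips
# ---------------------------------------------------------------------------


def write_weight_matrix(W: WeightMatrix, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        W.to_frame().to_csv(fh, index_label="model")


def read_weight_matrix(path, catalog: ClassCatalog | Sequence[str] | None = None) -> WeightMatrix:
    df = pd.read_csv(path, comment="#", index_col="model")
    cat = as_catalog(tuple(df.columns) if catalog is None else catalog)
    return WeightMatrix(cat, tuple(df.index), df[list(cat.labels)].to_numpy(dtype=float))


def write_branch_weights(
    branch_weights: Mapping[str, Mapping[tuple[str, str], tuple[float, float]]],
    path,
    header_lines: Sequence[str] = (),
) -> None:
    rows = [
        (m, "_".join(pair), pair[0], wa, pair[1], wb)
        for m, per_pair in branch_weights.items()
        for pair, (wa, wb) in per_pair.items()
    ]
    df = pd.DataFrame(
        rows, columns=["model", "branch", "class_a", "weight_a", "class_b", "weight_b"]
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_branch_weights(path) -> dict[str, dict[tuple[str, str], tuple[float, float]]]:
    df = pd.read_csv(path, comment="#")
    out: dict[str, dict[tuple[str, str], tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.model, {})[(row.class_a, row.class_b)] = (
            float(row.weight_a),
            float(row.weight_b),
        )
    return out


def write_confusion(cm: ConfusionMatrix, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cm.to_frame().to_csv(fh, index_label="true\\predicted")


def read_confusion(path, catalog: ClassCatalog | Sequence[str] | None = None) -> ConfusionMatrix:
    df = pd.read_csv(path, comment="#", index_col=0)
    cat = as_catalog(tuple(df.columns) if catalog is None else catalog)
    return ConfusionMatrix(df[list(cat.labels)].loc[list(cat.labels)].to_numpy(), cat)
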