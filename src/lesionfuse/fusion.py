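"""Weighted decision-fusion ensembles for multi-class lesion classification.

Two architectures are implemented.

**Ensemble Model 1** (direct score fusion): each base model emits a
per-class score row for a sample; the fused score for class c is the
sum over models of (model's score for c) x (model's weight for c), and
the prediction is the argmax.  Weights are per-(model, class) and by
default are the model's per-class F1 measured on a validation split.

**Ensemble Model 2** (one-vs-one decomposition): each base model is
replaced by C(K, 2) pairwise binary models, one per class pair.  For a
sample, every branch emits a two-sided decision; the score for class c
is the weighted sum, over the K-1 branches whose pair contains c, of
the decision mass the branch gives to c.  Totals from all base models
are then summed and the argmax taken.  With unit weights this reduces
to plain vote counting over the pairwise branches.

Decisions may be *soft* (score rows summing to one, e.g. softmax
outputs) or *hard* (one-hot argmax); hard mode is obtained by applying
:func:`harden` before fusing.  Fused totals are never normalised by the
weight sums.  Ties resolve to the earliest class in catalog order and
are flagged on the result.

Weights are keyed by (model id, class name), never by positional
index, so catalog reorderings cannot silently misassign them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError
from .metrics import ConfusionMatrix, binary_metrics, build_confusion, per_class_f1

__all__ = [
    "ROW_SUM_TOL",
    "TIE_TOL",
    "ScoreVector",
    "PredictionMatrix",
    "WeightMatrix",
    "BinaryDecision",
    "Branch",
    "BinaryBranchSet",
    "FusionResult",
    "argmax_with_tiebreak",
    "harden",
    "fuse_model1",
    "score_network_binary",
    "fuse_model2",
    "estimate_weights_from_confusion",
    "estimate_binary_weights",
    "branch_set_from_decisions",
]

#: Tolerance for soft score rows summing to one.
ROW_SUM_TOL = 1e-9
#: Tolerance within which two fused scores count as tied.
TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreVector:
    """Per-class fused vote mass for one sample.

    Entries are nonnegative reals; the catalog fixes which classes must
    be present and the tie-break order of the argmax.
    """

    catalog: ClassCatalog
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in self.catalog if c not in self.scores]
        if missing:
            raise StructuralError(f"score vector is missing classes {missing!r}")
        for c in self.catalog:
            if self.scores[c] < 0:
                raise StructuralError(f"score for {c!r} is negative: {self.scores[c]}")
        object.__setattr__(self, "scores", {c: float(self.scores[c]) for c in self.catalog})

    def __getitem__(self, label: str) -> float:
        return self.scores[label]

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[c] for c in self.catalog], dtype=float)


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-model class-score rows for one sample (M models x K classes).

    In soft mode each row sums to one (within ``ROW_SUM_TOL``); a
    one-hot row is the hard special case.
    """

    catalog: ClassCatalog
    model_ids: tuple[str, ...]
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        ids = tuple(self.model_ids)
        if len(set(ids)) != len(ids) or not ids:
            raise StructuralError(f"model ids must be nonempty and unique: {ids!r}")
        if rows.shape != (len(ids), len(self.catalog)):
            raise StructuralError(
                f"prediction rows have shape {rows.shape}, expected "
                f"({len(ids)}, {len(self.catalog)})"
            )
        if np.any(rows < 0):
            raise StructuralError("prediction scores must be nonnegative")
        bad = np.abs(rows.sum(axis=1) - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            raise StructuralError(
                f"prediction rows for models {[ids[i] for i in np.flatnonzero(bad)]!r} "
                "do not sum to 1"
            )
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "model_ids", ids)

    @classmethod
    def from_dict(
        cls,
        rows: Mapping[str, Mapping[str, float]],
        catalog: ClassCatalog | Sequence[str] | None = None,
    ) -> "PredictionMatrix":
        cat = as_catalog(catalog)
        ids = tuple(rows)
        arr = np.array([[rows[m].get(c, np.nan) for c in cat] for m in ids], dtype=float)
        if np.any(np.isnan(arr)):
            raise StructuralError("every model row must cover every catalog class")
        return cls(cat, ids, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, index=list(self.model_ids), columns=list(self.catalog.labels))

    def hardened(self) -> "PredictionMatrix":
        """One-hot version of every row (catalog-order tie-break)."""
        hard = np.vstack([harden(r, self.catalog) for r in self.rows])
        return PredictionMatrix(self.catalog, self.model_ids, hard)


@dataclass(frozen=True)
class WeightMatrix:
    """Fusion weights w_ij in [0, 1], keyed by (model id, class name)."""

    catalog: ClassCatalog
    model_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        ids = tuple(self.model_ids)
        if w.shape != (len(ids), len(self.catalog)):
            raise StructuralError(
                f"weight matrix has shape {w.shape}, expected ({len(ids)}, {len(self.catalog)})"
            )
        if np.any(w < 0) or np.any(w > 1):
            raise StructuralError("weights must lie in [0, 1]")
        empty = np.flatnonzero(w.sum(axis=0) == 0)
        if empty.size:
            dead = [self.catalog.labels[i] for i in empty]
            raise StructuralError(f"classes {dead!r} have no positive weight in any model")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "model_ids", ids)

    @classmethod
    def from_dict(
        cls,
        entries: Mapping[str, Mapping[str, float]],
        catalog: ClassCatalog | Sequence[str] | None = None,
    ) -> "WeightMatrix":
        cat = as_catalog(catalog)
        ids = tuple(entries)
        arr = np.array([[entries[m].get(c, np.nan) for c in cat] for m in ids], dtype=float)
        if np.any(np.isnan(arr)):
            raise StructuralError("every model must carry a weight for every catalog class")
        return cls(cat, ids, arr)

    @classmethod
    def unit(
        cls, model_ids: Sequence[str], catalog: ClassCatalog | Sequence[str] | None = None
    ) -> "WeightMatrix":
        cat = as_catalog(catalog)
        return cls(cat, tuple(model_ids), np.ones((len(model_ids), len(cat))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.model_ids), columns=list(self.catalog.labels))


@dataclass(frozen=True)
class BinaryDecision:
    """Two-sided decision of one pairwise binary model for one sample."""

    pair: tuple[str, str]
    score_a: float
    score_b: float

    def __post_init__(self) -> None:
        if self.score_a < 0 or self.score_b < 0:
            raise StructuralError("binary decision scores must be nonnegative")
        if abs(self.score_a + self.score_b - 1.0) > ROW_SUM_TOL:
            raise StructuralError(
                f"binary decision for pair {self.pair!r} does not sum to 1: "
                f"{self.score_a} + {self.score_b}"
            )

    def score_for(self, label: str) -> float:
        if label == self.pair[0]:
            return self.score_a
        if label == self.pair[1]:
            return self.score_b
        raise StructuralError(f"class {label!r} is not in pair {self.pair!r}")

    def hardened(self) -> "BinaryDecision":
        # ties go to the first (catalog-earlier) class of the pair
        if self.score_a >= self.score_b:
            return BinaryDecision(self.pair, 1.0, 0.0)
        return BinaryDecision(self.pair, 0.0, 1.0)

    def winner(self) -> str:
        return self.pair[0] if self.score_a >= self.score_b else self.pair[1]


@dataclass(frozen=True)
class Branch:
    """One pairwise branch: its current decision plus two-sided weights."""

    decision: BinaryDecision
    weight_a: float
    weight_b: float

    def __post_init__(self) -> None:
        if self.weight_a < 0 or self.weight_b < 0:
            raise StructuralError(
                f"branch weights for pair {self.decision.pair!r} must be nonnegative"
            )

    def weight_for(self, label: str) -> float:
        if label == self.decision.pair[0]:
            return self.weight_a
        return self.weight_b


@dataclass(frozen=True)
class BinaryBranchSet:
    """The complete C(K, 2) pairwise branches of one base model."""

    catalog: ClassCatalog
    branches: Mapping[tuple[str, str], Branch]
    model_id: str = "model"

    def __post_init__(self) -> None:
        expected = self.catalog.pairs()
        got = set(self.branches)
        missing = [p for p in expected if p not in got]
        if missing:
            raise StructuralError(f"branch set is missing pairs {missing!r}")
        extra = got - set(expected)
        if extra:
            raise StructuralError(
                f"unexpected branch pairs {sorted(extra)!r}; pairs must be in catalog order"
            )
        for pair, branch in self.branches.items():
            if branch.decision.pair != pair:
                raise StructuralError(
                    f"branch keyed {pair!r} holds a decision for {branch.decision.pair!r}"
                )
        object.__setattr__(self, "branches", dict(self.branches))

    def hardened(self) -> "BinaryBranchSet":
        hard = {
            pair: Branch(b.decision.hardened(), b.weight_a, b.weight_b)
            for pair, b in self.branches.items()
        }
        return BinaryBranchSet(self.catalog, hard, self.model_id)


@dataclass(frozen=True)
class FusionResult:
    """Outcome of one fused prediction."""

    predicted: str
    scores: ScoreVector
    breakdown: pd.DataFrame = field(repr=False)
    tie: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def argmax_with_tiebreak(
    scores: ScoreVector | Mapping[str, float],
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> tuple[str, bool]:
    """Maximal-score class with deterministic catalog-order tie-break.

    Returns ``(class, tie_flag)``; the flag is set when another class
    comes within ``TIE_TOL`` of the maximum.
    """
    if isinstance(scores, ScoreVector):
        vec, cat = scores, scores.catalog
    else:
        cat = as_catalog(catalog)
        vec = ScoreVector(cat, dict(scores))
    arr = vec.as_array()
    best = int(np.argmax(arr))
    # np.argmax already returns the first maximum; detect near-ties explicitly
    tied = np.flatnonzero(arr >= arr[best] - TIE_TOL)
    winner_idx = int(tied[0])
    return cat.labels[winner_idx], bool(tied.size > 1)


def harden(
    row: Sequence[float] | Mapping[str, float],
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> np.ndarray:
    """One-hot a score row at its argmax (catalog-order tie-break)."""
    cat = as_catalog(catalog)
    if isinstance(row, Mapping):
        arr = np.array([row[c] for c in cat], dtype=float)
    else:
        arr = np.asarray(row, dtype=float)
    if arr.size == 0:
        raise StructuralError("cannot harden an empty score row")
    if np.any(arr < 0):
        raise StructuralError("scores must be nonnegative")
    out = np.zeros_like(arr)
    out[int(np.argmax(arr))] = 1.0
    return out


def fuse_model1(
    P: PredictionMatrix,
    W: WeightMatrix,
    mode: str = "soft",
) -> FusionResult:
    """Direct weighted score fusion across base models (Ensemble Model 1).

    ``scores[c] = sum_m P[m][c] * W[m][c]``; prediction is the argmax
    with catalog-order tie-break.  ``mode='hard'`` one-hots every model
    row first.

    The breakdown frame records each model's weighted contribution per
    class, so a prediction can be audited term by term.
    """
    if P.model_ids != W.model_ids:
        raise StructuralError(
            f"prediction and weight matrices disagree on model ids: "
            f"{P.model_ids!r} vs {W.model_ids!r}"
        )
    if P.catalog != W.catalog:
        raise StructuralError("prediction and weight matrices disagree on the catalog")
    if mode not in ("soft", "hard"):
        raise StructuralError(f"unknown decision mode {mode!r}; expected 'soft' or 'hard'")
    if mode == "hard":
        P = P.hardened()
    contrib = P.rows * W.weights
    totals = contrib.sum(axis=0)
    vec = ScoreVector(P.catalog, dict(zip(P.catalog.labels, totals)))
    predicted, tie = argmax_with_tiebreak(vec)
    breakdown = pd.DataFrame(contrib, index=list(P.model_ids), columns=list(P.catalog.labels))
    return FusionResult(predicted, vec, breakdown, tie)


def score_network_binary(branches: BinaryBranchSet, mode: str = "soft") -> ScoreVector:
    """Per-class weighted vote totals over one model's pairwise branches.

    Each class c accumulates, from the K-1 branches whose pair contains
    it, (decision mass for c) x (branch weight for c); branches not
    containing c contribute zero.
    """
    if mode not in ("soft", "hard"):
        raise StructuralError(f"unknown decision mode {mode!r}; expected 'soft' or 'hard'")
    if mode == "hard":
        branches = branches.hardened()
    totals = {c: 0.0 for c in branches.catalog}
    for pair, branch in branches.branches.items():
        for label in pair:
            totals[label] += branch.decision.score_for(label) * branch.weight_for(label)
    return ScoreVector(branches.catalog, totals)


def fuse_model2(
    per_model_branches: Sequence[BinaryBranchSet],
    mode: str = "soft",
) -> FusionResult:
    """One-vs-one decomposition fusion across base models (Ensemble Model 2).

    The class totals are the sum over base models of the per-model
    pairwise vote totals of :func:`score_network_binary`; prediction is
    the argmax with catalog-order tie-break.  With all branch weights 1
    this is plain (possibly soft) vote counting over every branch of
    every model.
    """
    if not per_model_branches:
        raise StructuralError("at least one base model's branch set is required")
    catalog = per_model_branches[0].catalog
    for bs in per_model_branches[1:]:
        if bs.catalog != catalog:
            raise StructuralError("all branch sets must share one catalog")
    totals = np.zeros(len(catalog))
    rows: list[pd.Series] = []
    for bs in per_model_branches:
        vec = score_network_binary(bs, mode=mode)
        arr = vec.as_array()
        totals += arr
        effective = bs.hardened() if mode == "hard" else bs
        for pair, branch in effective.branches.items():
            row = {c: 0.0 for c in catalog}
            for label in pair:
                row[label] = branch.decision.score_for(label) * branch.weight_for(label)
            rows.append(pd.Series(row, name=(bs.model_id, "_".join(pair))))
    vec = ScoreVector(catalog, dict(zip(catalog.labels, totals)))
    predicted, tie = argmax_with_tiebreak(vec)
    breakdown = pd.DataFrame(rows)
    breakdown.index = pd.MultiIndex.from_tuples(breakdown.index, names=["model", "branch"])
    return FusionResult(predicted, vec, breakdown, tie)


def estimate_weights_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Per-class fusion weights for one model: its validation F1 scores.

    The model's validation confusion matrix yields one F1 per class;
    those F1 values become the model's column of the weight matrix, so
    a model votes on each class in proportion to how well it told that
    class apart on held-out data.
    """
    if cm.total == 0:
        raise StructuralError("cannot estimate weights from an empty confusion matrix")
    return per_class_f1(cm)


def estimate_binary_weights(
    validation_decisions: Mapping[tuple[str, str], Sequence[tuple[BinaryDecision, str]]],
    catalog: ClassCatalog | Sequence[str] | None = None,
    policy: str = "f1",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Two-sided weights for every pairwise branch from labelled validation data.

    For each branch (a, b), decisions are hardened and tallied into a
    2x2 confusion matrix against the true labels.  Under the default
    ``'f1'`` policy the weight of class c is c's F1 in that table;
    ``'accuracy'`` gives both sides the branch accuracy; ``'unit'``
    returns 1.0 everywhere.  A branch whose validation samples cover
    only one of its two classes cannot be scored and falls back to unit
    weights with a warning.
    """
    cat = as_catalog(catalog)
    if policy not in ("f1", "accuracy", "unit"):
        raise StructuralError(f"unknown weight policy {policy!r}")
    weights: dict[tuple[str, str], tuple[float, float]] = {}
    for pair in cat.pairs():
        if pair not in validation_decisions:
            raise StructuralError(f"no validation decisions supplied for branch {pair!r}")
        samples = validation_decisions[pair]
        if not samples:
            raise StructuralError(f"branch {pair!r} has no validation samples")
        if policy == "unit":
            weights[pair] = (1.0, 1.0)
            continue
        a, b = pair
        truths = [t for _, t in samples]
        if set(truths) < {a, b}:
            warnings.warn(
                f"branch {pair!r} saw only class {truths[0]!r} in validation; "
                "falling back to unit weights",
                stacklevel=2,
            )
            weights[pair] = (1.0, 1.0)
            continue
        preds = [d.hardened().winner() for d, _ in samples]
        cm = build_confusion(truths, preds, ClassCatalog(pair))
        tp = int(cm.counts[0, 0])
        fn = int(cm.counts[0, 1])
        fp = int(cm.counts[1, 0])
        tn = int(cm.counts[1, 1])
        m_a = binary_metrics(tp, tn, fp, fn)
        if policy == "accuracy":
            weights[pair] = (m_a.acc, m_a.acc)
        else:
            m_b = binary_metrics(tn, tp, fn, fp)  # b as the positive class
            weights[pair] = (m_a.f1, m_b.f1)
    return weights


def branch_set_from_decisions(
    decisions: Mapping[tuple[str, str], BinaryDecision],
    branch_weights: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    catalog: ClassCatalog | Sequence[str] | None = None,
    model_id: str = "model",
) -> BinaryBranchSet:
    """Assemble a BinaryBranchSet from per-pair decisions and weights.

    Omitted weights default to unit weights on every branch.
    """
    cat = as_catalog(catalog)
    branches = {}
    for pair in cat.pairs():
        if pair not in decisions:
            raise StructuralError(f"missing decision for branch {pair!r}")
        wa, wb = (1.0, 1.0) if branch_weights is None else branch_weights[pair]
        branches[pair] = Branch(decisions[pair], wa, wb)
    return BinaryBranchSet(cat, branches, model_id)
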