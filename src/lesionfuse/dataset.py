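"""Dataset preparation for lesion-image archives.

Dermoscopy archives often photograph one lesion several times, mix
classes of very different prevalence, and need augmentation to balance
training counts.  The pipeline implemented here, in order:

1. **lesion-level deduplication** — every lesion that appears in more
   than one image is removed entirely, so each remaining record is a
   unique lesion;
2. **class filtering** — keep only the classes under study (by default
   mel, nv, bcc, bkl; rarer classes such as akiec, df and vasc are
   dropped);
3. **majority-class downsampling** — a seeded random fraction of the
   dominant nv class is discarded (default 20%);
4. **stratified splitting** — 75% training / 15% validation / 10% test
   by default, allocated per class with largest-remainder rounding;
5. **augmentation planning** — integer per-image copy counts that hit
   an exact per-class target, differing by at most one within a class;
6. **pairwise subsets** — the C(K, 2) two-class record subsets that
   train one-vs-one binary branches.

Metadata travels as CSV with columns ``image_id,lesion_id,label,partition``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import ClassCatalog, as_catalog
from .errors import StructuralError

__all__ = [
    "ImageRecord",
    "SplitSpec",
    "PARTITIONS",
    "deduplicate_lesions",
    "filter_classes",
    "downsample_class",
    "split_records",
    "plan_augmentation",
    "pair_subsets",
    "read_metadata",
    "write_metadata",
]

PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class ImageRecord:
    """One archive image: image id, lesion id, class label, split assignment."""

    image_id: str
    lesion_id: str
    label: str
    partition: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.image_id or not self.lesion_id:
            raise StructuralError("image and lesion ids must be nonempty")
        if self.partition not in PARTITIONS + ("unassigned",):
            raise StructuralError(f"unknown partition {self.partition!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions, seed, and stratification flag."""

    train: float = 0.75
    validation: float = 0.15
    test: float = 0.10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fracs):
            raise StructuralError(f"split fractions must be positive: {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise StructuralError(f"split fractions must sum to 1: {fracs}")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train, self.validation, self.test)


def deduplicate_lesions(records: Sequence[ImageRecord]) -> list[ImageRecord]:
    """Drop every lesion photographed more than once — all of its images.

    Keeping any single image of a multi-image lesion risks near-duplicate
    leakage across splits, so the whole lesion is removed instead.
    """
    counts = Counter(r.lesion_id for r in records)
    return [r for r in records if counts[r.lesion_id] == 1]


def filter_classes(records: Sequence[ImageRecord], keep: Iterable[str]) -> list[ImageRecord]:
    """Keep only records whose label is in ``keep``, preserving order."""
    keep_set = set(keep)
    if not keep_set:
        raise StructuralError("the set of classes to keep must be nonempty")
    return [r for r in records if r.label in keep_set]


def downsample_class(
    records: Sequence[ImageRecord],
    target_class: str,
    discard_fraction: float,
    seed: int,
) -> list[ImageRecord]:
    """Randomly discard ``round(discard_fraction * n)`` records of one class.

    Other classes pass through untouched; output order follows input
    order.  Deterministic for a fixed seed.
    """
    if not 0 <= discard_fraction < 1:
        raise StructuralError(f"discard fraction must be in [0, 1), got {discard_fraction}")
    target_idx = [i for i, r in enumerate(records) if r.label == target_class]
    if not target_idx:
        raise StructuralError(f"no records of class {target_class!r} to downsample")
    n_drop = int(round(discard_fraction * len(target_idx)))
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(target_idx, size=n_drop, replace=False).tolist())
    return [r for i, r in enumerate(records) if i not in dropped]


def _largest_remainder(
    n: int,
    fractions: Sequence[float],
    deficits: Sequence[float] | None = None,
) -> list[int]:
    """Allocate n items to bins by quota floors plus largest remainders.

    Ties in remainder break toward the bin with the larger running
    ``deficit`` (how far the bin lags its global quota across earlier
    allocations), then toward the earlier bin (train before validation
    before test).  This keeps stratified per-class roundings from all
    drifting the same way, so global totals also match the fractions.
    """
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(sizes)
    deficits = [0.0] * len(fractions) if deficits is None else list(deficits)
    order = sorted(
        range(len(fractions)),
        key=lambda i: (-(quotas[i] - sizes[i]), -deficits[i], i),
    )
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_records(records: Sequence[ImageRecord], spec: SplitSpec) -> list[ImageRecord]:
    """Assign every record to train/validation/test per the split spec.

    With ``stratified=True`` the fractions are applied within each
    class, so per-class counts match the fractions to within the +-1
    of largest-remainder rounding.  Output preserves input order;
    identical seed and input give identical partitions.
    """
    if not records:
        raise StructuralError("cannot split an empty record sequence")
    rng = np.random.default_rng(spec.seed)
    assignment: dict[int, str] = {}
    if spec.stratified:
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            groups.setdefault(r.label, []).append(i)
        group_keys = sorted(groups)  # deterministic iteration regardless of input order
    else:
        groups = {"_all": list(range(len(records)))}
        group_keys = ["_all"]
    allocated = [0.0] * len(PARTITIONS)
    total_allocated = 0
    for key in group_keys:
        idx = np.array(groups[key])
        rng.shuffle(idx)
        deficits = [total_allocated * f - a for f, a in zip(spec.fractions, allocated)]
        sizes = _largest_remainder(len(idx), spec.fractions, deficits)
        for p, s in enumerate(sizes):
            allocated[p] += s
        total_allocated += len(idx)
        cursor = 0
        for part, size in zip(PARTITIONS, sizes):
            for i in idx[cursor : cursor + size]:
                assignment[int(i)] = part
            cursor += size
    return [replace(r, partition=assignment[i]) for i, r in enumerate(records)]


def plan_augmentation(
    class_counts: Mapping[str, int],
    targets: Mapping[str, int],
) -> dict[str, list[int]]:
    """Per-image augmented-copy counts that hit each class target exactly.

    Returns, per class, a list of integer multiplicities (extra copies
    per original image, originals excluded) such that
    ``count + sum(multiplicities) == target`` and multiplicities within
    a class differ by at most one.
    """
    plan: dict[str, list[int]] = {}
    for cls, count in class_counts.items():
        if cls not in targets:
            raise StructuralError(f"no augmentation target for class {cls!r}")
        target = targets[cls]
        if count <= 0:
            raise StructuralError(f"class {cls!r} has no original images")
        if target < count:
            raise StructuralError(
                f"target {target} for class {cls!r} is below the original count {count}"
            )
        extra = target - count
        base, rem = divmod(extra, count)
        plan[cls] = [base + 1] * rem + [base] * (count - rem)
    return plan


def pair_subsets(
    records: Sequence[ImageRecord],
    catalog: ClassCatalog | Sequence[str] | None = None,
) -> dict[tuple[str, str], list[ImageRecord]]:
    """The C(K, 2) two-class record subsets used to train pairwise branches."""
    cat = as_catalog(catalog)
    if len(cat) < 2:
        raise StructuralError("pairwise subsets need a catalog of at least two classes")
    return {
        pair: [r for r in records if r.label in pair]
        for pair in cat.pairs()
    }


def read_metadata(path) -> list[ImageRecord]:
    """Read image metadata CSV (``image_id,lesion_id,label[,partition]``)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"image_id", "lesion_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralError(f"metadata CSV is missing columns {sorted(missing)!r}")
    if "partition" not in df.columns:
        df["partition"] = "unassigned"
    df["partition"] = df["partition"].fillna("unassigned")
    return [
        ImageRecord(row.image_id, row.lesion_id, row.label, row.partition)
        for row in df.itertuples(index=False)
    ]


def write_metadata(records: Sequence[ImageRecord], path, header_comment: str | None = None) -> None:
    """Write image metadata CSV, optionally with a ``#``-prefixed provenance line."""
    df = pd.DataFrame(
        [(r.image_id, r.lesion_id, r.label, r.partition) for r in records],
        columns=["image_id", "lesion_id", "label", "partition"],
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
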