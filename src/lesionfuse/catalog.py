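"""Class catalog: the ordered set of lesion classes for one run.

The catalog order is fixed for a run and doubles as the tie-break
priority: when fused scores tie, the earliest class in catalog order
wins.  The default order places melanoma first, so ties resolve toward
the clinically most dangerous class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

from .errors import StructuralError

DEFAULT_CLASSES: tuple[str, ...] = ("mel", "nv", "bcc", "bkl")


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered, unique class labels.

    Parameters
    ----------
    labels
        Class names in priority order.  Must be nonempty and unique.
    """

    labels: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise StructuralError("catalog must contain at least one class")
        if len(set(labels)) != len(labels):
            raise StructuralError(f"catalog labels must be unique: {labels!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise StructuralError(f"unknown class {label!r}; catalog is {self.labels!r}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """All C(K, 2) unordered class pairs, each in catalog order."""
        return list(combinations(self.labels, 2))

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        """Order a class pair by catalog priority."""
        ia, ib = self.index(a), self.index(b)
        if ia == ib:
            raise StructuralError(f"a class pair needs two distinct classes, got {a!r} twice")
        return (a, b) if ia < ib else (b, a)


def as_catalog(value: "ClassCatalog | Sequence[str] | None") -> ClassCatalog:
    """Coerce a label sequence (or None for the default) to a ClassCatalog."""
    if value is None:
        return ClassCatalog()
    if isinstance(value, ClassCatalog):
        return value
    return ClassCatalog(tuple(value))
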