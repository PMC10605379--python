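"""Run configuration: JSON in, validated dataclass out, hashable for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .catalog import ClassCatalog, DEFAULT_CLASSES
from .errors import StructuralError

__all__ = ["RunConfig", "load_config", "save_config"]

FUSION_MODES = ("model1", "model2")
DECISION_MODES = ("soft", "hard")
WEIGHT_POLICIES = ("f1", "accuracy", "unit")


@dataclass(frozen=True)
class RunConfig:
    """One run's knobs: catalog order, fusion/decision mode, weight policy, seed.

    The catalog order also fixes the tie-break priority of fused
    predictions, which is why it is part of the recorded configuration.
    """

    catalog: tuple[str, ...] = DEFAULT_CLASSES
    fusion_mode: str = "model1"
    decision_mode: str = "soft"
    weight_policy: str = "f1"
    seed: int = 0
    tie_break: str = "catalog-order"  # informational; the only implemented rule

    def __post_init__(self) -> None:
        ClassCatalog(tuple(self.catalog))  # validates uniqueness / nonemptiness
        object.__setattr__(self, "catalog", tuple(self.catalog))
        if self.fusion_mode not in FUSION_MODES:
            raise StructuralError(f"fusion_mode must be one of {FUSION_MODES}, got {self.fusion_mode!r}")
        if self.decision_mode not in DECISION_MODES:
            raise StructuralError(f"decision_mode must be one of {DECISION_MODES}")
        if self.weight_policy not in WEIGHT_POLICIES:
            raise StructuralError(f"weight_policy must be one of {WEIGHT_POLICIES}")

    def class_catalog(self) -> ClassCatalog:
        return ClassCatalog(self.catalog)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"seed={self.seed} config_hash={self.hash()}"]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise StructuralError(f"unknown configuration keys {sorted(unknown)!r}")
    if "catalog" in raw:
        raw["catalog"] = tuple(raw["catalog"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
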