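"""Feature schema: which clinical variable goes to which processing group.

The model routes tabular clinical variables through four attention groups —
blood chemistry/hematology (G1), biochemical markers (G2), endocrine and
immunological markers (G3), lifestyle and demographic factors (G4) — while
the two neurological markers (serum β2-microglobulin and the MMSE cognitive
score) bypass the groups and feed the trunk directly.  A
:class:`FeatureSchema` pins the column order, the group routing and an
optional clinical reference range per feature; the bundled default schema
covers the full 81-variable panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

CATEGORIES = frozenset(
    {
        "demographic",
        "blood_chemistry",
        "biochemical",
        "endocrine_immune",
        "neurological",
        "lifestyle",
    }
)
GROUPS = ("G1_blood", "G2_biochem", "G3_endocrine", "G4_lifestyle")
DIRECT = "DIRECT"
VALUE_KINDS = frozenset({"continuous", "binary", "ordinal"})


class SchemaError(ValueError):
    """Raised when a feature schema violates its contract."""


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical variable: its category, group routing and reference range."""

    name: str
    category: str
    group: str
    value_kind: str = "continuous"
    reference_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"feature {self.name!r}: unknown category {self.category!r}"
            )
        if self.group != DIRECT and self.group not in GROUPS:
            raise SchemaError(f"feature {self.name!r}: unknown group {self.group!r}")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(
                f"feature {self.name!r}: unknown value kind {self.value_kind!r}"
            )
        if self.category == "neurological" and self.group != DIRECT:
            # β2mg and MMSE are fed to the trunk directly, never via a group.
            raise SchemaError(
                f"neurological marker {self.name!r} must carry group {DIRECT}"
            )
        if self.reference_range is not None:
            low, high = self.reference_range
            if not (float(low) < float(high)):
                raise SchemaError(
                    f"feature {self.name!r}: reference range must satisfy "
                    f"low < high, got ({low}, {high})"
                )


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature definitions plus the group → members index."""

    features: tuple[FeatureSpec, ...]
    group_index: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise SchemaError(f"duplicate feature name {name!r}")
            seen.add(name)
        index: dict[str, tuple[str, ...]] = {}
        for g in (*GROUPS, DIRECT):
            members = tuple(f.name for f in self.features if f.group == g)
            if members:
                index[g] = members
        object.__setattr__(self, "group_index", index)

    # -- convenience accessors -------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def direct_names(self) -> tuple[str, ...]:
        return self.group_index.get(DIRECT, ())

    @property
    def active_groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if g in self.group_index)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def column_indices(self, names: Iterable[str]) -> list[int]:
        """Positions of ``names`` in schema column order."""
        order = {n: i for i, n in enumerate(self.names)}
        return [order[n] for n in names]


def _spec_from_mapping(entry: dict) -> FeatureSpec:
    try:
        name = str(entry["name"])
        category = str(entry["category"])
        group = str(entry["group"])
    except KeyError as exc:  # pragma: no cover - config authoring error
        raise SchemaError(f"feature entry missing required key: {exc}") from exc
    kind = str(entry.get("kind", entry.get("value_kind", "continuous")))
    rng = entry.get("range", entry.get("reference_range"))
    ref = None if rng is None else (float(rng[0]), float(rng[1]))
    return FeatureSpec(
        name=name, category=category, group=group, value_kind=kind, reference_range=ref
    )


def load_schema(config_path: str | Path) -> FeatureSchema:
    """Read a YAML feature-schema config.

    The file holds a top-level ``features`` list; each entry gives ``name``,
    ``category``, ``group``, and optionally ``kind`` and ``range: [low, high]``.
    Duplicate names and unknown groups/categories raise :class:`SchemaError`.
    """
    path = Path(config_path)
    with path.open("r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "features" not in payload:
        raise SchemaError(f"{path}: expected a mapping with a 'features' list")
    entries = payload["features"]
    if not isinstance(entries, list) or not entries:
        raise SchemaError(f"{path}: 'features' must be a non-empty list")
    return FeatureSchema(tuple(_spec_from_mapping(e) for e in entries))


def default_schema() -> FeatureSchema:
    """The bundled 81-variable clinical panel (four groups + β2mg/MMSE DIRECT)."""
    ref = resources.files("adattn").joinpath("data/default_schema.yaml")
    with resources.as_file(ref) as path:
        return load_schema(path)
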