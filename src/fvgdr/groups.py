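"""Food-group taxonomy and item-to-group mapping.

The fruit-and-vegetable component of the Global Dietary Recommendation
(GDR) score counts consumption of six mutually exclusive food groups:
vitamin A-rich vegetables, dark green leafy vegetables, other vegetables,
vitamin A-rich fruits, citrus, and other fruits.  Item-level recall data
are assigned to these groups through a country-specific mapping file that
also flags *sentinel* items — the commonly consumed foods listed under each
questionnaire question.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "FoodGroup",
    "GROUPS",
    "GROUP_CODES",
    "FoodMapping",
    "MappingEntry",
    "load_mapping",
    "classify_item",
    "normalize_item_name",
]


class FoodGroup(Enum):
    """The six fruit-and-vegetable groups of the GDR score, in fixed order."""

    VA_VEG = "va_veg"
    DGLV = "dglv"
    OTHER_VEG = "other_veg"
    VA_FRUIT = "va_fruit"
    CITRUS = "citrus"
    OTHER_FRUIT = "other_fruit"

    @property
    def label(self) -> str:
        return _LABELS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_LABELS = {
    FoodGroup.VA_VEG: "Vitamin A-rich vegetables",
    FoodGroup.DGLV: "Dark green leafy vegetables",
    FoodGroup.OTHER_VEG: "Other vegetables",
    FoodGroup.VA_FRUIT: "Vitamin A-rich fruits",
    FoodGroup.CITRUS: "Citrus",
    FoodGroup.OTHER_FRUIT: "Other fruits",
}

#: The six groups in canonical order.
GROUPS: tuple[FoodGroup, ...] = tuple(FoodGroup)

#: Lower-case group codes, used as column names in tabular interfaces.
GROUP_CODES: tuple[str, ...] = tuple(g.value for g in GROUPS)

_WS = re.compile(r"\s+")


def normalize_item_name(name: str) -> str:
    """Case-fold and collapse whitespace so lookups are exact but forgiving."""
    return _WS.sub(" ", str(name).strip()).casefold()


def _parse_group(token: object) -> FoodGroup:
    key = str(token).strip()
    try:
        return FoodGroup[key.upper()]
    except KeyError:
        raise ValueError(
            f"unknown food-group code {key!r}; expected one of "
            f"{', '.join(g.name for g in GROUPS)}"
        ) from None


@dataclass(frozen=True)
class MappingEntry:
    group: FoodGroup
    sentinel: bool


@dataclass
class FoodMapping:
    """Item name -> (food group, sentinel flag), keyed by normalized name."""

    entries: dict[str, MappingEntry] = field(default_factory=dict)
    country_tag: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_item_name(name) in self.entries

    def group_of(self, name: str) -> Optional[FoodGroup]:
        entry = self.entries.get(normalize_item_name(name))
        return entry.group if entry is not None else None

    def is_sentinel(self, name: str) -> bool:
        entry = self.entries.get(normalize_item_name(name))
        return bool(entry.sentinel) if entry is not None else False

    def add(self, name: str, group: FoodGroup, sentinel: bool) -> None:
        """Add one item; duplicate names must agree on the group.

        Duplicates with consistent groups merge into a single entry; the
        sentinel flag is OR-ed (an item listed once as sentinel stays one).
        """
        key = normalize_item_name(name)
        existing = self.entries.get(key)
        if existing is not None:
            if existing.group is not group:
                raise ValueError(
                    f"item {name!r} mapped to both {existing.group.name} "
                    f"and {group.name}"
                )
            sentinel = sentinel or existing.sentinel
        self.entries[key] = MappingEntry(group, bool(sentinel))

    def items_in(self, group: FoodGroup, sentinel_only: bool = False) -> list[str]:
        return [
            name
            for name, entry in self.entries.items()
            if entry.group is group and (entry.sentinel or not sentinel_only)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with columns ``item,group,sentinel``."""
        rows = [
            {"item": name, "group": entry.group.name, "sentinel": int(entry.sentinel)}
            for name, entry in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["item", "group", "sentinel"])


def load_mapping(path: Union[str, Path], country_tag: str = "") -> FoodMapping:
    """Read an ``item,group,sentinel`` CSV into a :class:`FoodMapping`.

    Raises ``ValueError`` naming the offending row for unknown group codes,
    non-binary sentinel flags, or duplicate items with conflicting groups.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("item", "group", "sentinel") if c not in df.columns]
    if missing:
        raise ValueError(f"mapping file {path} is missing column(s): {', '.join(missing)}")
    mapping = FoodMapping(country_tag=country_tag)
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            group = _parse_group(row.group)
        except ValueError as exc:
            raise ValueError(f"{path}, row {pos}: {exc}") from None
        sentinel_raw = str(row.sentinel).strip()
        if sentinel_raw not in {"0", "1"}:
            raise ValueError(
                f"{path}, row {pos}: sentinel must be 0 or 1, got {sentinel_raw!r}"
            )
        try:
            mapping.add(row.item, group, sentinel_raw == "1")
        except ValueError as exc:
            raise ValueError(f"{path}, row {pos}: {exc}") from None
    return mapping


def classify_item(name: str, mapping: FoodMapping) -> Optional[FoodGroup]:
    """Return the food group of ``name``, or ``None`` for non-F&V items.

    Unmapped items (staples, animal foods, ...) are simply outside the six
    fruit-and-vegetable groups; they never raise.
    """
    return mapping.group_of(name)
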