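"""Binary food-group indicators and the FV-GDR score.

Both assessment methods are reduced to the same representation: six
binary consumption flags per respondent-day.  The questionnaire (DQQ)
yields them directly from its yes/no answers; the quantitative 24-h
recall (24hR) yields them by aggregating item-level gram amounts into the
six groups.  The FV-GDR score is the number of groups consumed (0-6).

Recall-derived indicators support three modes:

``threshold``
    a group counts only if some item reaches ``min_grams`` (default 15 g)
    — the primary definition, matching the questionnaire's focus on
    non-trivial portions;
``all_quantities``
    any positive amount counts (sensitivity analysis without the 15 g
    filter);
``sentinel_only``
    like ``threshold`` but restricted to sentinel items (sensitivity
    analysis limited to the questionnaire's own food lists).

The 15 g rule is applied per food item: rows of the same item within a
respondent-day are summed first (robust to data-entry granularity), then
compared with the threshold.  An optional ``aggregate="group"`` variant
applies the threshold to the group-day total instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .groups import GROUPS, GROUP_CODES, FoodGroup, FoodMapping, normalize_item_name

__all__ = [
    "SCORING_MODES",
    "DQQResponse",
    "RecallRecord",
    "ScoringOptions",
    "IndicatorSet",
    "ScoreRecord",
    "indicators_from_dqq",
    "indicators_from_recall",
    "fv_gdr",
    "total_intake_g",
    "meets_cutoff",
    "dqq_indicator_frame",
    "recall_indicator_frame",
    "recall_intake_series",
    "unmapped_item_count",
]

SCORING_MODES = ("threshold", "all_quantities", "sentinel_only")


@dataclass(frozen=True)
class DQQResponse:
    """One respondent-day of questionnaire answers (six yes/no items)."""

    respondent_id: str
    day: int
    answers: Mapping[FoodGroup, bool]

    def __post_init__(self) -> None:
        missing = [g.name for g in GROUPS if g not in self.answers]
        if missing:
            raise ValueError(f"DQQ response missing answer(s) for: {', '.join(missing)}")


@dataclass(frozen=True)
class RecallRecord:
    """One food item consumed on one recall day, in grams."""

    respondent_id: str
    day: int
    item: str
    grams: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.grams) or self.grams < 0:
            raise ValueError(f"grams must be finite and non-negative, got {self.grams}")


@dataclass(frozen=True)
class ScoringOptions:
    mode: str = "threshold"
    min_grams: float = 15.0
    aggregate: str = "item"  # "item": per-item 15 g rule; "group": per group-day sum

    def __post_init__(self) -> None:
        if self.mode not in SCORING_MODES:
            raise ValueError(f"mode must be one of {SCORING_MODES}, got {self.mode!r}")
        if self.aggregate not in ("item", "group"):
            raise ValueError(f"aggregate must be 'item' or 'group', got {self.aggregate!r}")
        if self.mode in ("threshold", "sentinel_only") and not self.min_grams > 0:
            raise ValueError("min_grams must be > 0 for threshold/sentinel_only modes")


@dataclass(frozen=True)
class IndicatorSet:
    """Six binary consumption flags for one respondent-day and method."""

    respondent_id: str
    day: int
    method: str  # "DQQ" or "R24H"
    flags: Mapping[FoodGroup, int]

    def __post_init__(self) -> None:
        missing = [g.name for g in GROUPS if g not in self.flags]
        if missing:
            raise ValueError(f"indicator set missing flag(s) for: {', '.join(missing)}")
        bad = {g.name: v for g, v in self.flags.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"flags must be 0/1, got {bad}")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(int(self.flags[g]) for g in GROUPS)


@dataclass(frozen=True)
class ScoreRecord:
    respondent_id: str
    day: int
    method: str
    fv_gdr: int
    total_grams: Optional[float] = None  # recall only; questionnaire has no quantities

    def __post_init__(self) -> None:
        if not 0 <= self.fv_gdr <= len(GROUPS):
            raise ValueError(f"fv_gdr must lie in [0, {len(GROUPS)}], got {self.fv_gdr}")


def indicators_from_dqq(resp: DQQResponse) -> IndicatorSet:
    """Questionnaire answers are already the indicators: yes -> 1, no -> 0."""
    flags = {g: int(bool(resp.answers[g])) for g in GROUPS}
    return IndicatorSet(resp.respondent_id, resp.day, "DQQ", flags)


def indicators_from_recall(
    records: Sequence[RecallRecord],
    mapping: FoodMapping,
    opts: ScoringOptions = ScoringOptions(),
    *,
    respondent_id: Optional[str] = None,
    day: Optional[int] = None,
) -> IndicatorSet:
    """Aggregate item-level recall rows of one respondent-day into flags.

    ``respondent_id``/``day`` are only needed for an empty record list (a
    day with no food rows, which scores 0 on every group).  Unmapped items
    are not fruits or vegetables and are ignored.
    """
    keys = {(r.respondent_id, r.day) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple respondent-days: {sorted(keys)}")
    if keys:
        rid, d = next(iter(keys))
        if respondent_id is not None and respondent_id != rid:
            raise ValueError("respondent_id argument conflicts with the records")
        respondent_id, day = rid, d
    if respondent_id is None or day is None:
        raise ValueError("empty record list: pass respondent_id and day explicitly")

    flags = {g: 0 for g in GROUPS}
    if opts.mode == "all_quantities":
        for rec in records:
            group = mapping.group_of(rec.item)
            if group is not None and rec.grams > 0:
                flags[group] = 1
    else:
        # Sum duplicate rows of an item first, then apply the 15 g rule.
        sums: dict[tuple[FoodGroup, str], float] = {}
        for rec in records:
            group = mapping.group_of(rec.item)
            if group is None:
                continue
            if opts.mode == "sentinel_only" and not mapping.is_sentinel(rec.item):
                continue
            key = (group, "" if opts.aggregate == "group" else normalize_item_name(rec.item))
            sums[key] = sums.get(key, 0.0) + rec.grams
        for (group, _), total in sums.items():
            if total >= opts.min_grams:
                flags[group] = 1
    return IndicatorSet(respondent_id, day, "R24H", flags)


def fv_gdr(ind: IndicatorSet) -> int:
    """Number of fruit-and-vegetable groups consumed: sum of the six flags."""
    return int(sum(ind.flags[g] for g in GROUPS))


def total_intake_g(records: Iterable[RecallRecord], mapping: FoodMapping) -> float:
    """Grams/day of fruits and vegetables: all mapped items, no 15 g filter."""
    return float(sum(r.grams for r in records if mapping.group_of(r.item) is not None))


def meets_cutoff(score: int, k: int) -> bool:
    """Whether a score reaches the adherence cut-off (score >= k)."""
    if not 0 <= score <= len(GROUPS):
        raise ValueError(f"score must lie in [0, {len(GROUPS)}], got {score}")
    return score >= k


# ---------------------------------------------------------------------------
# Table-level counterparts used by the validation pipeline.  Indicator
# frames are indexed by (respondent_id, day) with one 0/1 column per group.
# ---------------------------------------------------------------------------

def dqq_indicator_frame(dqq: pd.DataFrame) -> pd.DataFrame:
    """Wide 0/1 indicator frame from a questionnaire table."""
    df = dqq.set_index(["respondent_id", "day"])[list(GROUP_CODES)].astype("int8")
    return df.sort_index()


def _mapped_recall(recall: pd.DataFrame, mapping: FoodMapping) -> pd.DataFrame:
    df = recall.copy()
    norm = df["item"].map(normalize_item_name)
    group = {name: e.group.value for name, e in mapping.entries.items()}
    sentinel = {name: e.sentinel for name, e in mapping.entries.items()}
    df["_norm"] = norm
    df["_group"] = norm.map(group)
    df["_sentinel"] = norm.map(lambda s: sentinel.get(s, False)).astype(bool)
    return df


def unmapped_item_count(recall: pd.DataFrame, mapping: FoodMapping) -> int:
    """Number of recall rows whose item is not in the F&V mapping."""
    return int(_mapped_recall(recall, mapping)["_group"].isna().sum())


def recall_indicator_frame(
    recall: pd.DataFrame,
    mapping: FoodMapping,
    opts: ScoringOptions = ScoringOptions(),
) -> pd.DataFrame:
    """Wide 0/1 indicator frame from an item-level recall table.

    Every (respondent_id, day) present in the input — even one that only
    contains unmapped staples — yields a row; absent groups are 0.
    """
    universe = pd.MultiIndex.from_frame(
        recall[["respondent_id", "day"]].drop_duplicates()
    ).sort_values()
    df = _mapped_recall(recall, mapping)
    df = df[df["_group"].notna()]
    if opts.mode == "sentinel_only":
        df = df[df["_sentinel"]]
    if opts.mode == "all_quantities":
        hits = df[df["grams"] > 0]
        eligible = hits[["respondent_id", "day", "_group"]].drop_duplicates()
    else:
        item_key = "_group" if opts.aggregate == "group" else "_norm"
        sums = (
            df.groupby(["respondent_id", "day", "_group", item_key], sort=False)["grams"]
            .sum()
            .reset_index()
        )
        eligible = sums[sums["grams"] >= opts.min_grams][
            ["respondent_id", "day", "_group"]
        ].drop_duplicates()
    wide = (
        eligible.assign(flag=1)
        .pivot_table(index=["respondent_id", "day"], columns="_group", values="flag",
                     fill_value=0, aggfunc="max")
        .reindex(universe, fill_value=0)
        .reindex(columns=list(GROUP_CODES), fill_value=0)
        .astype("int8")
    )
    wide.index.names = ["respondent_id", "day"]
    wide.columns.name = None
    return wide.sort_index()


def recall_intake_series(recall: pd.DataFrame, mapping: FoodMapping) -> pd.Series:
    """Total F&V grams per respondent-day (all mapped items, no filter)."""
    df = _mapped_recall(recall, mapping)
    fv = df[df["_group"].notna()]
    totals = fv.groupby(["respondent_id", "day"])["grams"].sum()
    universe = pd.MultiIndex.from_frame(
        recall[["respondent_id", "day"]].drop_duplicates()
    ).sort_values()
    out = totals.reindex(universe, fill_value=0.0).astype(float)
    out.index.names = ["respondent_id", "day"]
    out.name = "fv_grams"
    return out.sort_index()
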