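"""Table readers/writers and pipeline configuration.

All interfaces are plain CSV: the questionnaire table
(``respondent_id,day,va_veg,dglv,other_veg,va_fruit,citrus,other_fruit``
with 0/1 cells), the item-level recall table
(``respondent_id,day,item,grams``), and the mapping file
(``item,group,sentinel``).  Validation is strict — a malformed cell is a
hard error naming the row — because silent coercion of dietary data is a
classic source of irreproducible results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .groups import GROUP_CODES, FoodMapping, load_mapping
from .scoring import SCORING_MODES, ScoringOptions
from .validation import FVGDRValidation, ValidationResults

__all__ = [
    "DQQ_COLUMNS",
    "RECALL_COLUMNS",
    "PipelineConfig",
    "load_config",
    "read_dqq_table",
    "read_recall_table",
    "write_dqq_table",
    "write_recall_table",
    "run_validation",
]

DQQ_COLUMNS = ["respondent_id", "day"] + list(GROUP_CODES)
RECALL_COLUMNS = ["respondent_id", "day", "item", "grams"]


@dataclass
class PipelineConfig:
    """Analysis thresholds and scoring options for one validation run."""

    mode: str = "threshold"
    min_grams: float = 15.0
    aggregate: str = "item"
    alpha: float = 0.05
    meaningful_pp: float = 10.0
    cutoff: int = 3
    who_grams: float = 400.0
    seed: int = 12345
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.mode not in SCORING_MODES:
            raise ValueError(f"mode must be one of {SCORING_MODES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.meaningful_pp <= 0:
            raise ValueError("meaningful_pp must be > 0")

    def scoring_options(self) -> ScoringOptions:
        return ScoringOptions(mode=self.mode, min_grams=self.min_grams,
                              aggregate=self.aggregate)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**data)


def read_dqq_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a questionnaire table."""
    df = pd.read_csv(path)
    missing = [c for c in DQQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing column(s): {', '.join(missing)}")
    df = df[DQQ_COLUMNS].copy()
    df["respondent_id"] = df["respondent_id"].astype(str)
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    for code in GROUP_CODES:
        col = pd.to_numeric(df[code], errors="coerce")
        bad = df.index[~col.isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"{path}: column {code!r} must be 0/1; "
                f"offending data row(s): {[int(i) + 2 for i in bad[:5]]}"
            )
        df[code] = col.astype(int)
    dup = df.duplicated(subset=["respondent_id", "day"])
    if dup.any():
        first = df.loc[dup, ["respondent_id", "day"]].iloc[0]
        raise ValueError(
            f"{path}: duplicated (respondent_id, day) = "
            f"({first['respondent_id']}, {first['day']})"
        )
    return df


def read_recall_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an item-level recall table."""
    df = pd.read_csv(path)
    missing = [c for c in RECALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing column(s): {', '.join(missing)}")
    df = df[RECALL_COLUMNS].copy()
    df["respondent_id"] = df["respondent_id"].astype(str)
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    grams = pd.to_numeric(df["grams"], errors="coerce")
    bad = df.index[grams.isna() | (grams < 0)]
    if len(bad):
        raise ValueError(
            f"{path}: grams must be non-negative numbers; "
            f"offending data row(s): {[int(i) + 2 for i in bad[:5]]}"
        )
    df["grams"] = grams.astype(float)
    df["item"] = df["item"].astype(str)
    return df


def write_dqq_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[DQQ_COLUMNS].to_csv(path, index=False)


def write_recall_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[RECALL_COLUMNS].to_csv(path, index=False)


def run_validation(
    config: PipelineConfig,
    dqq: pd.DataFrame,
    recall: pd.DataFrame,
    mapping: FoodMapping,
) -> ValidationResults:
    """Run the full battery for one dataset under a pipeline config."""
    model = FVGDRValidation(
        dqq,
        recall,
        mapping,
        options=config.scoring_options(),
        alpha=config.alpha,
        meaningful_pp=config.meaningful_pp,
        report_cutoff=config.cutoff,
        who_grams=config.who_grams,
        seed=config.seed,
    )
    return model.fit()
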