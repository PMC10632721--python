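"""Synthetic dual-method recall data with known ground truth.

The generator emulates the structure of a two-day, two-method dietary
validation study: each respondent contributes two recall days; true
consumption of each food group is Bernoulli with a respondent-level
propensity (random effect on the logit scale) inducing within-person
dependence; consumed groups yield 1-3 food items with lognormal gram
amounts (floored at 15 g for regular portions, or scaled into (2, 14) g
for a configurable fraction of "small-portion" items); each item is a
sentinel item with a configurable probability.  The recall table records
items and grams faithfully; the questionnaire answer is the latent
consumption flag flipped 0->1 with a per-group false-positive probability
and 1->0 with a false-negative probability.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .groups import GROUPS, GROUP_CODES, FoodGroup, FoodMapping

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "scenario_presets",
    "build_default_mapping",
]

GroupMap = Union[float, Mapping[FoodGroup, float]]

#: Items per group in the generated mapping (3 sentinel + 3 non-sentinel).
_ITEMS_PER_KIND = 3

#: Staple item present on every recall day; not a fruit or vegetable.
_STAPLE_ITEM = "rice"

_DEF_PREVALENCE = {
    FoodGroup.VA_VEG: 0.35,
    FoodGroup.DGLV: 0.75,
    FoodGroup.OTHER_VEG: 0.90,
    FoodGroup.VA_FRUIT: 0.20,
    FoodGroup.CITRUS: 0.25,
    FoodGroup.OTHER_FRUIT: 0.55,
}


def _as_group_map(value: GroupMap, name: str, lo: float, hi: float) -> dict[FoodGroup, float]:
    if isinstance(value, Mapping):
        out = {g: float(value.get(g, 0.0)) for g in GROUPS}
    else:
        out = {g: float(value) for g in GROUPS}
    for g, v in out.items():
        if not (lo <= v <= hi):
            raise ValueError(f"{name}[{g.name}] must lie in [{lo}, {hi}], got {v}")
    return out


@dataclass
class SimulationConfig:
    """All generator parameters; per-group fields accept a scalar or a dict."""

    n_respondents: int = 600
    days_per_respondent: int = 2
    group_prevalence: GroupMap = field(default_factory=lambda: dict(_DEF_PREVALENCE))
    within_person_sd: float = 0.8          # logit-scale propensity SD
    quantity_log_mean: GroupMap = math.log(70.0)   # lognormal mu of item grams
    quantity_log_sd: GroupMap = 0.5
    small_portion_prob: GroupMap = 0.0     # P(consumed item scaled below 15 g)
    fp_prob: GroupMap = 0.0                # questionnaire FP on true non-consumers
    fn_prob: GroupMap = 0.0                # questionnaire FN on true consumers
    sentinel_coverage: GroupMap = 0.8      # P(consumed item is a sentinel item)
    min_items: int = 1
    max_items: int = 3
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.n_respondents < 1 or self.days_per_respondent < 1:
            raise ValueError("counts must be >= 1")
        if self.within_person_sd < 0:
            raise ValueError("within_person_sd must be >= 0")
        if not 1 <= self.min_items <= self.max_items:
            raise ValueError("need 1 <= min_items <= max_items")
        self.group_prevalence = _as_group_map(self.group_prevalence, "group_prevalence", 0, 1)
        self.quantity_log_mean = _as_group_map(
            self.quantity_log_mean, "quantity_log_mean", -math.inf, math.inf
        )
        self.quantity_log_sd = _as_group_map(self.quantity_log_sd, "quantity_log_sd", 0, math.inf)
        self.small_portion_prob = _as_group_map(self.small_portion_prob, "small_portion_prob", 0, 1)
        self.fp_prob = _as_group_map(self.fp_prob, "fp_prob", 0, 1)
        self.fn_prob = _as_group_map(self.fn_prob, "fn_prob", 0, 1)
        self.sentinel_coverage = _as_group_map(self.sentinel_coverage, "sentinel_coverage", 0, 1)


@dataclass
class SimulatedDataset:
    """Paired questionnaire/recall tables, their mapping, and the truth ledger."""

    dqq_table: pd.DataFrame     # respondent_id, day, six 0/1 columns
    recall_table: pd.DataFrame  # respondent_id, day, item, grams
    mapping: FoodMapping
    truth: pd.DataFrame         # respondent_id, day, group, consumed, grams_total
    config: SimulationConfig


def build_default_mapping(country_tag: str = "synthetic") -> FoodMapping:
    """Mapping used by the generator: 3 sentinel + 3 other items per group."""
    mapping = FoodMapping(country_tag=country_tag)
    for g in GROUPS:
        for j in range(1, _ITEMS_PER_KIND + 1):
            mapping.add(f"{g.value}_sentinel_{j}", g, True)
            mapping.add(f"{g.value}_other_{j}", g, False)
    return mapping


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset; byte-identical tables for a given seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R, D, G = cfg.n_respondents, cfg.days_per_respondent, len(GROUPS)
    pi = np.array([cfg.group_prevalence[g] for g in GROUPS])
    phi = np.array([cfg.fp_prob[g] for g in GROUPS])
    nu = np.array([cfg.fn_prob[g] for g in GROUPS])
    mu = np.array([cfg.quantity_log_mean[g] for g in GROUPS])
    sd = np.array([cfg.quantity_log_sd[g] for g in GROUPS])
    p_small = np.array([cfg.small_portion_prob[g] for g in GROUPS])
    p_sent = np.array([cfg.sentinel_coverage[g] for g in GROUPS])

    ids = np.array([f"r{i + 1:05d}" for i in range(R)])

    # Latent consumption: respondent propensity shared across days.
    u = rng.normal(0.0, cfg.within_person_sd, R)
    eta = _logit(pi)[None, None, :] + u[:, None, None]
    prob = 1.0 / (1.0 + np.exp(-eta))
    consumed = rng.random((R, D, G)) < prob

    # Questionnaire answers: flip the latent flag with group-level errors.
    flip_up = rng.random((R, D, G)) < phi[None, None, :]
    flip_dn = rng.random((R, D, G)) < nu[None, None, :]
    answer = np.where(consumed, ~flip_dn, flip_up)

    dqq = pd.DataFrame(
        {
            "respondent_id": np.repeat(ids, D),
            "day": np.tile(np.arange(1, D + 1), R),
        }
    )
    for k, code in enumerate(GROUP_CODES):
        dqq[code] = answer[:, :, k].reshape(-1).astype(int)

    # Recall items for each consumed (respondent, day, group) cell.
    cells = np.argwhere(consumed)  # (M, 3): respondent, day, group indices
    M = len(cells)
    k_items = rng.integers(cfg.min_items, cfg.max_items + 1, M)
    cell_of_item = np.repeat(np.arange(M), k_items)
    gi = cells[cell_of_item, 2]
    T = len(cell_of_item)
    is_sent = rng.random(T) < p_sent[gi]
    which = rng.integers(1, _ITEMS_PER_KIND + 1, T)
    raw = rng.lognormal(mu[gi], sd[gi], T)
    small = rng.random(T) < p_small[gi]
    small_grams = rng.uniform(2.0, 14.0, T)
    grams = np.round(np.where(small, small_grams, np.maximum(raw, 15.0)), 1)

    codes = np.array(GROUP_CODES)
    kind = np.where(is_sent, "sentinel", "other")
    items = np.char.add(
        np.char.add(np.char.add(codes[gi], "_"), kind),
        np.char.add("_", which.astype(str)),
    )
    fv_rows = pd.DataFrame(
        {
            "respondent_id": ids[cells[cell_of_item, 0]],
            "day": cells[cell_of_item, 1] + 1,
            "item": items,
            "grams": grams,
        }
    )
    staple = pd.DataFrame(
        {
            "respondent_id": np.repeat(ids, D),
            "day": np.tile(np.arange(1, D + 1), R),
            "item": _STAPLE_ITEM,
            "grams": np.round(rng.lognormal(5.5, 0.4, R * D), 1),
        }
    )
    recall = (
        pd.concat([fv_rows, staple], ignore_index=True)
        .sort_values(["respondent_id", "day", "item"], kind="mergesort")
        .reset_index(drop=True)
    )

    # Truth ledger: latent flags plus true gram totals per group-day.
    grams_cell = np.zeros(M)
    np.add.at(grams_cell, cell_of_item, grams)
    truth = pd.DataFrame(
        {
            "respondent_id": np.repeat(ids, D * G),
            "day": np.tile(np.repeat(np.arange(1, D + 1), G), R),
            "group": np.tile(codes, R * D),
            "consumed": consumed.reshape(-1).astype(int),
        }
    )
    totals = np.zeros((R, D, G))
    totals[cells[:, 0], cells[:, 1], cells[:, 2]] = grams_cell
    truth["grams_total"] = totals.reshape(-1).round(1)

    return SimulatedDataset(
        dqq_table=dqq,
        recall_table=recall,
        mapping=build_default_mapping(),
        truth=truth,
        config=cfg,
    )


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named generator configurations.

    ``no_error``
        error-free baseline: questionnaire answers equal threshold-mode
        recall indicators exactly.
    ``hanoi_like``
        under-reporting of the high-variety groups (other vegetables /
        other fruits) through questionnaire false negatives and low
        sentinel coverage, with mild over-reporting of leafy greens and
        citrus.
    ``ibadan_like``
        heavy over-reporting of vitamin A-rich vegetables driven by
        habitual small portions (sauce ingredients under 15 g) plus
        questionnaire false positives; fruits nearly error-free.
    """
    no_error = SimulationConfig(
        small_portion_prob=0.0,
        fp_prob=0.0,
        fn_prob=0.0,
        sentinel_coverage=1.0,
        seed=101,
    )
    hanoi_like = SimulationConfig(
        group_prevalence={
            FoodGroup.VA_VEG: 0.30,
            FoodGroup.DGLV: 0.80,
            FoodGroup.OTHER_VEG: 0.92,
            FoodGroup.VA_FRUIT: 0.15,
            FoodGroup.CITRUS: 0.30,
            FoodGroup.OTHER_FRUIT: 0.75,
        },
        fn_prob={
            FoodGroup.VA_VEG: 0.05,
            FoodGroup.DGLV: 0.05,
            FoodGroup.OTHER_VEG: 0.28,
            FoodGroup.VA_FRUIT: 0.05,
            FoodGroup.CITRUS: 0.05,
            FoodGroup.OTHER_FRUIT: 0.30,
        },
        fp_prob={
            FoodGroup.VA_VEG: 0.04,
            FoodGroup.DGLV: 0.12,
            FoodGroup.OTHER_VEG: 0.04,
            FoodGroup.VA_FRUIT: 0.04,
            FoodGroup.CITRUS: 0.12,
            FoodGroup.OTHER_FRUIT: 0.04,
        },
        sentinel_coverage={
            FoodGroup.VA_VEG: 0.85,
            FoodGroup.DGLV: 0.85,
            FoodGroup.OTHER_VEG: 0.45,
            FoodGroup.VA_FRUIT: 0.85,
            FoodGroup.CITRUS: 0.85,
            FoodGroup.OTHER_FRUIT: 0.50,
        },
        small_portion_prob=0.05,
        seed=102,
    )
    ibadan_like = SimulationConfig(
        group_prevalence={
            FoodGroup.VA_VEG: 0.95,
            FoodGroup.DGLV: 0.85,
            FoodGroup.OTHER_VEG: 0.90,
            FoodGroup.VA_FRUIT: 0.12,
            FoodGroup.CITRUS: 0.10,
            FoodGroup.OTHER_FRUIT: 0.40,
        },
        small_portion_prob={
            FoodGroup.VA_VEG: 0.60,
            FoodGroup.DGLV: 0.05,
            FoodGroup.OTHER_VEG: 0.05,
            FoodGroup.VA_FRUIT: 0.02,
            FoodGroup.CITRUS: 0.02,
            FoodGroup.OTHER_FRUIT: 0.02,
        },
        fp_prob={
            FoodGroup.VA_VEG: 0.30,
            FoodGroup.DGLV: 0.12,
            FoodGroup.OTHER_VEG: 0.10,
            FoodGroup.VA_FRUIT: 0.02,
            FoodGroup.CITRUS: 0.02,
            FoodGroup.OTHER_FRUIT: 0.02,
        },
        fn_prob=0.02,
        sentinel_coverage=0.85,
        seed=103,
    )
    return {"no_error": no_error, "hanoi_like": hanoi_like, "ibadan_like": ibadan_like}
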