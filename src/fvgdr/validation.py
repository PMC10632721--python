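"""End-to-end dual-method validation: model object and fitted results.

`FVGDRValidation` is built from a questionnaire table, an item-level
recall table and a food-group mapping; `fit()` runs the full battery —
per-group prevalence differences and agreement statistics, the paired
Wilcoxon test on total scores, random-intercept standardized slopes of
gram intake on each method's score, the dependent-correlation comparison,
and the adherence cut-off analysis — and returns a `ValidationResults`
carrying estimates, uncertainties and a `summary()` table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union


import pandas as pd

from . import agreement as agr
from . import inference as inf
from .groups import GROUPS, FoodMapping, load_mapping
from .scoring import (
    ScoringOptions,
    dqq_indicator_frame,
    recall_indicator_frame,
    recall_intake_series,
    unmapped_item_count,
)

__all__ = ["FVGDRValidation", "ValidationResults", "GROUP_TABLE_COLUMNS"]

logger = logging.getLogger("fvgdr")

GROUP_TABLE_COLUMNS = [
    "group", "p_dqq", "p_r24h", "diff_pp", "p_value", "meaningful",
    "a", "b", "c", "d",
    "agreement_pct", "fp_pct", "fn_pct", "sensitivity", "specificity",
]


class _stage:
    """Attach the pipeline stage name to any error raised inside it."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> "_stage":
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, _StageError):
            raise _StageError(f"stage '{self.name}': {exc}") from exc
        return False


class _StageError(RuntimeError):
    pass


@dataclass
class ValidationResults:
    """Fitted validation battery for one dataset."""

    group_results: list[dict]
    wilcoxon: inf.WilcoxonResult
    beta_r24h: inf.MixedModelFit
    beta_dqq: inf.MixedModelFit
    correlations: inf.CorrelationTriple
    correlation_comparison: inf.DependentCorrelationComparison
    cutoff_dqq: inf.CutoffResult
    cutoff_r24h: inf.CutoffResult
    n_matched: int
    n_respondents: int
    log: dict = field(default_factory=dict)

    @property
    def group_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.group_results, columns=GROUP_TABLE_COLUMNS)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and not math.isfinite(x):
                return None
            return x

        def dmap(d: dict) -> dict:
            return {k: clean(v) for k, v in d.items()}

        return {
            "groups": [dmap(g) for g in self.group_results],
            "wilcoxon": dmap(asdict(self.wilcoxon)),
            "beta_st": {
                "r24h": dmap(asdict(self.beta_r24h)),
                "dqq": dmap(asdict(self.beta_dqq)),
            },
            "correlations": dmap(asdict(self.correlations)),
            "correlation_comparison": dmap(asdict(self.correlation_comparison)),
            "cutoff": {
                "dqq": dmap(asdict(self.cutoff_dqq)),
                "r24h": dmap(asdict(self.cutoff_r24h)),
            },
            "n_matched": self.n_matched,
            "n_respondents": self.n_respondents,
            "log": self.log,
        }

    def summary(self) -> str:
        """Human-readable report (percentages to one decimal)."""
        lines = []
        lines.append("FV-GDR validation: questionnaire (DQQ) vs. 24-h recall reference")
        lines.append("=" * 72)
        lines.append(
            f"matched observations: {self.n_matched} "
            f"({self.n_respondents} respondents)"
        )
        lines.append("")
        tab = self.group_table.copy()
        for col in ("p_dqq", "p_r24h", "diff_pp", "agreement_pct", "fp_pct", "fn_pct"):
            tab[col] = tab[col].map(lambda v: f"{v:.1f}")
        for col in ("sensitivity", "specificity"):
            tab[col] = tab[col].map(lambda v: "NA" if not math.isfinite(v) else f"{v:.2f}")
        tab["p_value"] = tab["p_value"].map(
            lambda v: "NA" if not math.isfinite(v) else f"{v:.3g}"
        )
        lines.append(tab.to_string(index=False))
        lines.append("")
        w = self.wilcoxon
        lines.append(
            f"Wilcoxon paired (DQQ - 24hR score): W = {w.statistic:.1f}, "
            f"p = {w.p_value:.3g}, median diff = {w.median_diff:g}"
        )
        for name, b in (("24hR", self.beta_r24h), ("DQQ", self.beta_dqq)):
            lines.append(
                f"beta_st intake ~ {name} score: {b.beta_st:.2f} "
                f"(95% CI {b.ci_low:.2f}, {b.ci_high:.2f}); "
                f"sigma_u = {b.sigma_u:.2f}, sigma_e = {b.sigma_e:.2f}"
            )
        c, d = self.correlations, self.correlation_comparison
        lines.append(
            f"correlations: r(intake, 24hR) = {c.r12:.2f}, "
            f"r(intake, DQQ) = {c.r13:.2f}, r(24hR, DQQ) = {c.r23:.2f}"
        )
        lines.append(
            f"dependent-correlation comparison: z = {d.z:.2f}, p = {d.p_value:.3g}, "
            f"95% CI for r12 - r13 ({d.zou_low:.2f}, {d.zou_high:.2f})"
        )
        for name, co in (("DQQ", self.cutoff_dqq), ("24hR", self.cutoff_r24h)):
            lines.append(
                f"optimal {name}-score cut-off for >= "
                f"{self.log.get('who_grams', 400)} g/d: {co.cutoff:g} "
                f"(Youden J = {co.criterion_value:.2f}); "
                f"% at/above cut-off {self.log.get('report_cutoff', 3)}: "
                f"DQQ {co.prop_dqq_above:.1f}, 24hR {co.prop_r24h_above:.1f}"
            )
        return "\n".join(lines)

    def save(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write the report as CSV + JSON (deterministic formatting)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "csv": outdir / "validation_report.csv",
            "json": outdir / "validation_report.json",
        }
        tab = self.group_table.copy()
        for col in ("p_dqq", "p_r24h", "diff_pp", "agreement_pct", "fp_pct", "fn_pct"):
            tab[col] = tab[col].round(1)
        for col in ("sensitivity", "specificity"):
            tab[col] = tab[col].round(3)
        tab["p_value"] = tab["p_value"].map(
            lambda v: "" if not math.isfinite(v) else f"{v:.4g}"
        )
        tab.to_csv(paths["csv"], index=False)
        with open(paths["json"], "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        return paths


class FVGDRValidation:
    """Dual-method validation model for one country/dataset.

    Parameters
    ----------
    dqq : DataFrame
        Questionnaire table: ``respondent_id, day`` plus six 0/1 columns.
    recall : DataFrame
        Item-level recall table: ``respondent_id, day, item, grams``.
    mapping : FoodMapping
        Item -> food-group dictionary with sentinel flags.
    options : ScoringOptions
        Recall scoring mode and gram threshold (default: 15 g rule).
    alpha, meaningful_pp
        Significance level and percentage-point threshold for flagging a
        prevalence difference as meaningful.
    report_cutoff, who_grams
        Integer adherence cut-off to tabulate, and the WHO gram threshold
        (400 g/day) used to label intake for the cut-off search.
    """

    def __init__(
        self,
        dqq: pd.DataFrame,
        recall: pd.DataFrame,
        mapping: FoodMapping,
        options: ScoringOptions = ScoringOptions(),
        *,
        alpha: float = 0.05,
        meaningful_pp: float = 10.0,
        report_cutoff: int = 3,
        who_grams: float = 400.0,
        seed: Optional[int] = None,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if meaningful_pp <= 0:
            raise ValueError("meaningful_pp must be > 0")
        self.dqq = dqq
        self.recall = recall
        self.mapping = mapping
        self.options = options
        self.alpha = alpha
        self.meaningful_pp = meaningful_pp
        self.report_cutoff = report_cutoff
        self.who_grams = who_grams
        self.seed = seed

    @classmethod
    def from_csv(
        cls,
        dqq_path: Union[str, Path],
        recall_path: Union[str, Path],
        mapping_path: Union[str, Path],
        **kwargs,
    ) -> "FVGDRValidation":
        from .io import read_dqq_table, read_recall_table

        return cls(
            read_dqq_table(dqq_path),
            read_recall_table(recall_path),
            load_mapping(mapping_path),
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, dataset, **kwargs) -> "FVGDRValidation":
        return cls(dataset.dqq_table, dataset.recall_table, dataset.mapping, **kwargs)

    def fit(self) -> ValidationResults:
        opts = self.options
        with _stage("scoring"):
            ind_dqq = dqq_indicator_frame(self.dqq)
            ind_r24h = recall_indicator_frame(self.recall, self.mapping, opts)
            n_unmapped = unmapped_item_count(self.recall, self.mapping)
        with _stage("matching"):
            dq, rc = agr.match_indicator_frames(ind_dqq, ind_r24h)
            dropped = (len(ind_dqq) - len(dq)) + (len(ind_r24h) - len(rc))
            if dropped:
                logger.info("dropped %d unmatched respondent-day observations", dropped)
        with _stage("agreement"):
            group_results = []
            for g in GROUPS:
                t = agr.crosstab(dq, rc, g)
                stats = agr.agreement_stats(t)
                prev = agr.prevalence_comparison(
                    dq, rc, g, alpha=self.alpha, meaningful_pp=self.meaningful_pp
                )
                group_results.append(
                    {
                        "group": g.value,
                        "p_dqq": prev.p_dqq,
                        "p_r24h": prev.p_r24h,
                        "diff_pp": prev.diff_pp,
                        "p_value": prev.p_value,
                        "meaningful": bool(prev.meaningful),
                        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                        "agreement_pct": stats.agreement_pct,
                        "fp_pct": stats.fp_pct,
                        "fn_pct": stats.fn_pct,
                        "sensitivity": stats.sensitivity,
                        "specificity": stats.specificity,
                    }
                )
        with _stage("scores"):
            score_dqq = dq.sum(axis=1).astype(float)
            score_r24h = rc.sum(axis=1).astype(float)
            intake = recall_intake_series(self.recall, self.mapping).reindex(
                dq.index, fill_value=0.0
            )
            resp = dq.index.get_level_values("respondent_id").to_numpy()
            wil = inf.wilcoxon_paired(score_dqq.to_numpy(), score_r24h.to_numpy())
        with _stage("mixed models"):
            beta_r24h = inf.mixed_beta_st(score_r24h.to_numpy(), intake.to_numpy(), resp)
            beta_dqq = inf.mixed_beta_st(score_dqq.to_numpy(), intake.to_numpy(), resp)
        with _stage("correlation comparison"):
            triple = inf.CorrelationTriple.from_data(
                intake.to_numpy(), score_r24h.to_numpy(), score_dqq.to_numpy()
            )
            comp = inf.compare_dependent_correlations(triple, alpha=self.alpha)
        with _stage("cutoff analysis"):
            cut_dqq = inf.cutoff_analysis(
                score_dqq.to_numpy(), intake.to_numpy(), self.who_grams,
                report_cutoff=self.report_cutoff,
                scores_dqq=score_dqq.to_numpy(), scores_r24h=score_r24h.to_numpy(),
            )
            cut_r24h = inf.cutoff_analysis(
                score_r24h.to_numpy(), intake.to_numpy(), self.who_grams,
                report_cutoff=self.report_cutoff,
                scores_dqq=score_dqq.to_numpy(), scores_r24h=score_r24h.to_numpy(),
            )
        log = {
            "mode": opts.mode,
            "min_grams": opts.min_grams,
            "aggregate": opts.aggregate,
            "alpha": self.alpha,
            "meaningful_pp": self.meaningful_pp,
            "report_cutoff": self.report_cutoff,
            "who_grams": self.who_grams,
            "seed": self.seed,
            "n_unmapped_recall_rows": n_unmapped,
            "n_dropped_unmatched": int(dropped),
        }
        return ValidationResults(
            group_results=group_results,
            wilcoxon=wil,
            beta_r24h=beta_r24h,
            beta_dqq=beta_dqq,
            correlations=triple,
            correlation_comparison=comp,
            cutoff_dqq=cut_dqq,
            cutoff_r24h=cut_r24h,
            n_matched=len(dq),
            n_respondents=int(pd.unique(resp).size),
            log=log,
        )
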