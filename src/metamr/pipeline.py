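"""End-to-end orchestration of the meta-analysis + MR pipeline.

Stage order: read/accept studies -> HWE per study -> per-model contrasts
and per-study odds ratios -> heterogeneity + fixed & random pooling with
model selection -> subgroup pooling (ethnicity, control source) ->
leave-one-out -> HWE-exclusion sensitivity -> Begg and Egger bias tests
-> Wald-ratio MR on the allele-model pooled estimate -> report bundle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import bias_diagnostics, meta_engine
from .effect_models import MODELS, annotate_hwe, compute_effects
from .errors import UsageError
from .meta_engine import ModelAnalysis
from .mr_estimator import wald_ratio
from .study_data import (
    EffectEstimate,
    GeneExposureEffect,
    StudyRecord,
    read_studies,
    write_report,
)

logger = logging.getLogger("metamr.pipeline")

#: Minimum number of studies for the bias tests to run.
MIN_K_BIAS = 3


@dataclass(frozen=True)
class RunConfig:
    """Knobs for a pipeline run; defaults follow the usual conventions."""

    models: tuple[str, ...] = MODELS
    q_p_threshold: float = meta_engine.Q_P_THRESHOLD
    i2_threshold: float = meta_engine.I2_THRESHOLD
    hwe_alpha: float = 0.05
    mr_beta: float = 0.158  # SD ln-tHcy per T allele
    mr_se_beta: float = 0.0
    se_mode: str = "simplified"
    continuity_correction: bool = True

    def __post_init__(self) -> None:
        if not self.models:
            raise UsageError("at least one genetic model must be selected")
        bad = [m for m in self.models if m not in MODELS]
        if bad:
            raise UsageError(f"unknown genetic model(s): {bad}")
        if not (0 < self.q_p_threshold < 1):
            raise UsageError("q_p_threshold must be in (0, 1)")
        if not (0 < self.i2_threshold < 100):
            raise UsageError("i2_threshold must be in (0, 100)")
        if not (0 < self.hwe_alpha < 1):
            raise UsageError("hwe_alpha must be in (0, 1)")


@dataclass
class AnalysisReport:
    """Everything a run produces, serializable via ``to_dict``."""

    n_studies: int
    hwe: dict[str, float]
    models: dict[str, ModelAnalysis]
    per_study: dict[str, list[EffectEstimate]]
    subgroups: dict[str, dict[str, dict[str, ModelAnalysis]]]
    leave_one_out: dict[str, list[tuple[str, meta_engine.PooledResult]]]
    hwe_sensitivity: dict[str, meta_engine.PooledResult | None]
    bias: dict[str, dict[str, bias_diagnostics.BiasTestResult]]
    mr: dict | None

    def to_dict(self) -> dict:
        def analysis_dict(a: ModelAnalysis) -> dict:
            return {
                "fixed": a.fixed.to_dict(),
                "random": a.random.to_dict(),
                "selected": a.selected,
                "primary": a.primary.to_dict(),
            }

        return {
            "n_studies": self.n_studies,
            "hwe": self.hwe,
            "models": {m: analysis_dict(a) for m, a in self.models.items()},
            "per_study": {
                m: [
                    {
                        "study_id": e.study_id,
                        "log_or": e.log_or,
                        "or": math.exp(e.log_or),
                        "se": e.se,
                        "corrected": e.corrected,
                    }
                    for e in effs
                ]
                for m, effs in self.per_study.items()
            },
            "subgroups": {
                strat: {
                    level: {m: analysis_dict(a) for m, a in per_model.items()}
                    for level, per_model in levels.items()
                }
                for strat, levels in self.subgroups.items()
            },
            "leave_one_out": {
                m: [
                    {"omitted": sid, **pooled.to_dict()}
                    for sid, pooled in rows
                ]
                for m, rows in self.leave_one_out.items()
            },
            "hwe_sensitivity": {
                m: (r.to_dict() if r is not None else None)
                for m, r in self.hwe_sensitivity.items()
            },
            "bias": {
                m: {name: res.to_dict() for name, res in tests.items()}
                for m, tests in self.bias.items()
            },
            "mr": self.mr,
        }


def run_pipeline(
    studies: Sequence[StudyRecord], config: RunConfig = RunConfig()
) -> AnalysisReport:
    """Run the full analysis on an in-memory study collection."""
    k = len(studies)
    if k < 1:
        raise UsageError("pipeline needs at least one study")
    logger.info("stage=read n_studies=%d", k)

    annotate_hwe(studies)
    n_out = sum(1 for s in studies if s.hwe_p is not None and s.hwe_p < config.hwe_alpha)
    logger.info("stage=hwe out_of_hwe=%d alpha=%g", n_out, config.hwe_alpha)

    models: dict[str, ModelAnalysis] = {}
    per_study: dict[str, list[EffectEstimate]] = {}
    subgroups: dict[str, dict[str, dict[str, ModelAnalysis]]] = {
        "ethnicity": {}, "control_source": {}
    }
    loo: dict[str, list[tuple[str, meta_engine.PooledResult]]] = {}
    hwe_sens: dict[str, meta_engine.PooledResult | None] = {}
    bias: dict[str, dict[str, bias_diagnostics.BiasTestResult]] = {}

    for model in config.models:
        effects = compute_effects(studies, model, correction=config.continuity_correction)
        if not effects:
            logger.warning("stage=effects model=%s: no estimable studies, skipping", model)
            continue
        per_study[model] = effects
        analysis = meta_engine.pool_auto(
            effects, model=model,
            q_p_threshold=config.q_p_threshold, i2_threshold=config.i2_threshold,
        )
        models[model] = analysis
        logger.info(
            "stage=pool model=%s k=%d or=%.4f selected=%s i2=%.1f",
            model, len(effects), analysis.primary.pooled_or, analysis.selected,
            analysis.fixed.i_squared,
        )

        for strat in ("ethnicity", "control_source"):
            for level, a in meta_engine.subgroup_analysis(studies, model, strat).items():
                subgroups[strat].setdefault(level, {})[model] = a

        if k >= 2:
            loo[model] = meta_engine.leave_one_out(studies, model)
        try:
            hwe_sens[model] = meta_engine.hwe_exclusion(studies, model, alpha=config.hwe_alpha)
        except UsageError as exc:
            logger.warning("stage=hwe_sensitivity model=%s skipped: %s", model, exc)
            hwe_sens[model] = None

        if len(effects) >= MIN_K_BIAS:
            bias[model] = {
                "egger": bias_diagnostics.egger_test(effects),
                "begg": bias_diagnostics.begg_test(effects),
            }
        else:
            logger.warning("stage=bias model=%s skipped: fewer than %d studies",
                           model, MIN_K_BIAS)

    mr_block = None
    if "allele" in models:
        gene_disease = _pooled_as_effect(models["allele"].primary)
        est = wald_ratio(
            gene_disease,
            GeneExposureEffect(beta=config.mr_beta, se_beta=config.mr_se_beta),
            se_mode=config.se_mode,
        )
        mr_block = est.to_dict()
        mr_block["gene_disease_or"] = models["allele"].primary.pooled_or
        mr_block["beta"] = config.mr_beta
        logger.info("stage=mr or_per_sd=%.4f", est.or_per_sd)
    else:
        logger.warning("stage=mr skipped: allele model not run or not estimable")

    return AnalysisReport(
        n_studies=k,
        hwe={s.study_id: float(s.hwe_p) for s in studies if s.hwe_p is not None},
        models=models,
        per_study=per_study,
        subgroups=subgroups,
        leave_one_out=loo,
        hwe_sensitivity=hwe_sens,
        bias=bias,
        mr=mr_block,
    )


def _pooled_as_effect(pooled: meta_engine.PooledResult) -> EffectEstimate:
    return EffectEstimate(
        study_id="pooled", model=pooled.model, log_or=pooled.pooled_log_or, se=pooled.se
    )


def run_pipeline_from_file(
    path: str | Path, config: RunConfig = RunConfig()
) -> AnalysisReport:
    return run_pipeline(read_studies(path), config)


def write_outputs(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the JSON report plus flat TSV companions; returns paths."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out_dir / "report.json"
    write_report(report, paths["report"])

    rows = []
    for m, a in report.models.items():
        for which in ("fixed", "random"):
            r = getattr(a, which)
            rows.append({"genetic_model": m, "selected": a.selected, **r.to_dict()})
    paths["models_tsv"] = out_dir / "pooled_models.tsv"
    pd.DataFrame(rows).to_csv(paths["models_tsv"], sep="\t", index=False)

    for m, effects in report.per_study.items():
        table = meta_engine.forest_table(effects, report.models[m].primary)
        p = out_dir / f"forest_{m}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"forest_{m}"] = p
        funnel = bias_diagnostics.funnel_data(effects)
        p = out_dir / f"funnel_{m}.tsv"
        funnel.to_csv(p, sep="\t", index=False)
        paths[f"funnel_{m}"] = p
    return paths
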