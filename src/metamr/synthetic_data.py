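"""Synthetic case-control study collections with known truth.

The generator emulates the kind of literature-extracted genotype-count
tables a meta-analysis consumes: K independent case-control studies of a
biallelic SNP, each drawing a control T-allele frequency, a study-level
per-allele log odds ratio (true mean effect plus Normal(0, tau)
between-study noise), and multinomial genotype counts.

Control genotype frequencies follow Hardy-Weinberg proportions unless
the study is designated a violator, in which case an inbreeding-style
distortion with coefficient F shifts mass from heterozygotes to
homozygotes:

    P(CC) = (1-q)^2 + F q (1-q),  P(CT) = 2 q (1-q) (1-F),
    P(TT) = q^2 + F q (1-q).

Case genotype frequencies are induced by multiplicative per-allele odds
weighting, w(g) proportional to P_control(g) * exp(delta * g) with g the
T-allele dose, the simplest generative model whose allele-contrast odds
ratio equals exp(delta).

Randomness is seeded per study (root seed + study index), so enlarging
K leaves earlier studies unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .effect_models import contrast, odds_ratio
from .errors import UsageError
from .study_data import GeneExposureEffect, GenotypeCounts, StudyRecord

logger = logging.getLogger("metamr.synthetic_data")

_GENE_EXPOSURE_STREAM = 999_983  # reserved sub-stream index, never a study index


@dataclass(frozen=True)
class SimulationConfig:
    """Study-collection truth and sampling design.

    Defaults mirror a 27-study literature meta-analysis of MTHFR C677T
    and gastric cancer: per-study arms of a few hundred subjects
    (roughly 230 cases / 300 controls on average), control T-allele
    frequencies between 0.2 and 0.5, a true per-allele OR of 1.16 with
    moderate between-study heterogeneity, and a gene-homocysteine effect
    of 0.158 SD ln-tHcy per T allele treated as a known constant.
    """

    k: int = 27
    n_cases_range: tuple[int, int] = (100, 400)
    n_controls_range: tuple[int, int] = (150, 500)
    maf_range: tuple[float, float] = (0.2, 0.5)
    true_log_or: float = math.log(1.16)
    tau: float = 0.1
    hwe_violation_fraction: float = 0.0
    inbreeding_f: float = 0.2
    small_study_bias: bool = False
    #: SE above which a study counts as "small" for the censoring rule.
    small_study_se: float = 0.15
    true_beta: float = 0.158
    true_se_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise UsageError("k must be at least 1")
        for name in ("n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise UsageError(f"{name} must satisfy 1 <= low <= high")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise UsageError("maf_range must lie strictly inside (0, 1)")
        if self.tau < 0 or self.true_se_beta < 0:
            raise UsageError("tau and true_se_beta must be non-negative")
        if not (0.0 <= self.hwe_violation_fraction <= 1.0):
            raise UsageError("hwe_violation_fraction must be in [0, 1]")
        if not (0.0 <= self.inbreeding_f < 1.0):
            raise UsageError("inbreeding_f must be in [0, 1)")


def paper27_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The shipped 27-study fixture configuration.

    Mirrors the structure of the motivating meta-analysis: 27 studies of
    mixed ethnicity and control source, 7 of which have controls out of
    Hardy-Weinberg equilibrium.
    """
    cfg = SimulationConfig(k=27, hwe_violation_fraction=7 / 27, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def _control_probs(q: float, f: float) -> np.ndarray:
    """Genotype probabilities (CC, CT, TT) for control T-allele freq q."""
    p = 1.0 - q
    het_shift = f * p * q
    return np.array([p * p + het_shift, 2 * p * q * (1 - f), q * q + het_shift])


def _case_probs(ctrl: np.ndarray, delta: float) -> np.ndarray:
    dose = np.array([0.0, 1.0, 2.0])
    w = ctrl * np.exp(delta * dose)
    return w / w.sum()


def _draw_study(
    config: SimulationConfig, index: int, violates_hwe: bool
) -> StudyRecord:
    rng = np.random.default_rng([config.seed, index])
    q = rng.uniform(*config.maf_range)
    n_cases = int(rng.integers(config.n_cases_range[0], config.n_cases_range[1] + 1))
    n_controls = int(rng.integers(config.n_controls_range[0], config.n_controls_range[1] + 1))
    ethnicity = rng.choice(["Asian", "Caucasian", "Mixed"], p=[0.5, 0.35, 0.15])
    control_source = rng.choice(["hospital", "population"], p=[0.6, 0.4])
    year = int(rng.integers(1995, 2016))
    f = config.inbreeding_f if violates_hwe else 0.0
    ctrl_p = _control_probs(q, f)

    max_attempts = 200
    for attempt in range(max_attempts):
        delta = config.true_log_or + config.tau * rng.standard_normal()
        case_p = _case_probs(ctrl_p, delta)
        case_counts = rng.multinomial(n_cases, case_p)
        ctrl_counts = rng.multinomial(n_controls, ctrl_p)
        record = StudyRecord(
            study_id=f"study_{index + 1:02d}",
            year=year,
            ethnicity=str(ethnicity),
            control_source=str(control_source),
            cases=GenotypeCounts(*(int(c) for c in case_counts)),
            controls=GenotypeCounts(*(int(c) for c in ctrl_counts)),
        )
        if not config.small_study_bias:
            return record
        # Small-study censoring: imprecise studies only reach the
        # literature when their estimate lands above the true mean.
        est = odds_ratio(
            contrast(record.cases, record.controls, "allele"), record.study_id, "allele"
        )
        if est is None or est.se <= config.small_study_se or est.log_or >= config.true_log_or:
            return record
    logger.warning("study %d: censoring rule exhausted %d attempts; keeping last draw",
                   index, max_attempts)
    return record


def simulate_studies(config: SimulationConfig) -> list[StudyRecord]:
    """Draw a study collection; deterministic given ``config.seed``."""
    n_violators = round(config.k * config.hwe_violation_fraction)
    return [_draw_study(config, i, violates_hwe=i < n_violators) for i in range(config.k)]


def simulate_gene_exposure(config: SimulationConfig) -> GeneExposureEffect:
    """Draw the gene-exposure summary statistic (an external GWAS stand-in)."""
    rng = np.random.default_rng([config.seed, _GENE_EXPOSURE_STREAM])
    beta = config.true_beta + config.true_se_beta * rng.standard_normal()
    return GeneExposureEffect(beta=float(beta), se_beta=config.true_se_beta)
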