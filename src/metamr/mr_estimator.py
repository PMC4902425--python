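"""Single-instrument Mendelian randomization via the Wald ratio.

With a variant that (i) associates with the exposure, (ii) affects the
outcome only through the exposure, and (iii) is independent of
confounders, the causal log odds ratio of disease per unit of exposure
is the ratio of the two genetic associations:

    log OR_disease/exposure = log OR_disease/allele / beta_exposure/allele

Here the exposure is natural-log plasma total homocysteine in SD units
and the instrument is the MTHFR C677T T allele, so the estimate reads
as the OR of disease per SD increase in ln-homocysteine.

Two delta-method standard errors are offered: ``simplified`` ignores
the sampling error of the gene-exposure beta (appropriate when it comes
from a GWAS far larger than the outcome sample), ``full`` propagates
both first-order terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .errors import UsageError
from .study_data import EffectEstimate, GeneExposureEffect

logger = logging.getLogger("metamr.mr_estimator")

#: |beta| below this (SD/allele) flags the instrument as weak.
WEAK_INSTRUMENT_FLOOR = 0.01

SE_MODES = ("simplified", "full")


@dataclass(frozen=True)
class MREstimate:
    """Causal effect of the exposure on disease risk, per SD of exposure."""

    log_or_per_sd: float
    se: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    se_mode: str
    weak_instrument: bool = False

    def to_dict(self) -> dict:
        return {
            "log_or_per_sd": self.log_or_per_sd,
            "se": self.se,
            "or_per_sd": self.or_per_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "se_mode": self.se_mode,
            "weak_instrument": self.weak_instrument,
        }


def wald_ratio(
    gene_disease: EffectEstimate,
    gene_exposure: GeneExposureEffect,
    se_mode: str = "simplified",
    weak_floor: float = WEAK_INSTRUMENT_FLOOR,
) -> MREstimate:
    """Wald-ratio MR estimate with a delta-method standard error.

    ``gene_disease`` should be the per-allele (allele-model) association
    so its units match the per-allele ``gene_exposure`` beta.
    """
    if se_mode not in SE_MODES:
        raise UsageError(f"se_mode must be one of {SE_MODES}, got {se_mode!r}")
    beta = gene_exposure.beta
    if beta == 0:
        raise UsageError("gene-exposure beta is zero: the instrument has no exposure effect")
    weak = abs(beta) < weak_floor
    if weak:
        logger.warning(
            "gene-exposure beta %.4g below weak-instrument floor %.4g", beta, weak_floor
        )
    point = gene_disease.log_or / beta
    if se_mode == "simplified":
        se = gene_disease.se / abs(beta)
    else:
        se = math.sqrt(
            gene_disease.se**2 / beta**2
            + gene_disease.log_or**2 * gene_exposure.se_beta**2 / beta**4
        )
    half = 1.96 * se
    p = 2.0 * float(stats.norm.sf(abs(point) / se)) if se > 0 else (0.0 if point else 1.0)
    return MREstimate(
        log_or_per_sd=float(point),
        se=float(se),
        or_per_sd=float(math.exp(point)),
        ci_low=float(math.exp(point - half)),
        ci_high=float(math.exp(point + half)),
        p_value=p,
        se_mode=se_mode,
        weak_instrument=weak,
    )


def se_from_ci(or_low: float, or_high: float) -> float:
    """Back out the log-OR standard error from a published 95% CI.

    Assumes the interval was formed as exp(log_or +/- 1.96 * se), so
    se = (ln(high) - ln(low)) / (2 * 1.96).
    """
    if not (0 < or_low < or_high):
        raise UsageError("need 0 < or_low < or_high")
    return (math.log(or_high) - math.log(or_low)) / (2 * 1.96)
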