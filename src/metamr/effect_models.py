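"""Genetic-model contrasts, per-study odds ratios, and the HWE check.

Each genetic model collapses the 3x2 genotype-by-status table into a
2x2 table:

==============  =======================================
allele          T alleles vs C alleles (gene counting)
homozygous      TT vs CC (heterozygotes excluded)
heterozygous    CT vs CC (TT excluded)
dominant        TT+CT vs CC
recessive       TT vs CT+CC
==============  =======================================

The allele model treats the two alleles of an individual as independent
observations, the conventional simplification in this literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import UsageError
from .study_data import EffectEstimate, GenotypeCounts, StudyRecord

logger = logging.getLogger("metamr.effect_models")

#: The five supported genetic-model contrasts.
MODELS = ("allele", "homozygous", "heterozygous", "dominant", "recessive")


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 table: (a, b) = exposed/unexposed cases, (c, d) = controls."""

    a: float
    b: float
    c: float
    d: float

    def swapped(self) -> "TwoByTwo":
        """Swap case and control rows (inverts the odds ratio)."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


def contrast(cases: GenotypeCounts, controls: GenotypeCounts, model: str) -> TwoByTwo:
    """Collapse genotype counts into the 2x2 table of the named model."""
    if model == "allele":
        return TwoByTwo(
            cases.n_t_alleles, cases.n_c_alleles, controls.n_t_alleles, controls.n_c_alleles
        )
    if model == "homozygous":
        return TwoByTwo(cases.n_tt, cases.n_cc, controls.n_tt, controls.n_cc)
    if model == "heterozygous":
        return TwoByTwo(cases.n_ct, cases.n_cc, controls.n_ct, controls.n_cc)
    if model == "dominant":
        return TwoByTwo(
            cases.n_tt + cases.n_ct, cases.n_cc, controls.n_tt + controls.n_ct, controls.n_cc
        )
    if model == "recessive":
        return TwoByTwo(
            cases.n_tt, cases.n_ct + cases.n_cc, controls.n_tt, controls.n_ct + controls.n_cc
        )
    raise UsageError(f"unknown genetic model {model!r}; expected one of {MODELS}")


def odds_ratio(
    table: TwoByTwo,
    study_id: str = "",
    model: str = "",
    correction: bool = True,
) -> EffectEstimate | None:
    """Log odds ratio and Woolf standard error for a 2x2 table.

    When any single cell is zero and ``correction`` is on, 0.5 is added
    to all four cells (Haldane-Anscombe) before taking logs.  A table
    with an entire row or column of zeros has no estimable odds ratio:
    ``None`` is returned and a warning logged, so callers drop the study
    from pooling.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise UsageError("2x2 cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.warning(
            "study %s (%s): empty row/column in 2x2 table, odds ratio not estimable",
            study_id or "<unnamed>",
            model or "<model>",
        )
        return None
    corrected = False
    if min(a, b, c, d) == 0:
        if not correction:
            logger.warning(
                "study %s (%s): zero cell and no continuity correction; not estimable",
                study_id or "<unnamed>",
                model or "<model>",
            )
            return None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(study_id=study_id, model=model, log_or=log_or, se=se, corrected=corrected)


def hwe_test(controls: GenotypeCounts) -> float:
    """Hardy-Weinberg chi-square test p-value for one control arm.

    Pearson chi-square on the three genotype cells against p^2 / 2pq / q^2
    expectations (1 df, because the allele frequency is estimated).
    Monomorphic samples carry no information and return p = 1.
    """
    n = controls.total
    if n < 1:
        raise UsageError("HWE test needs at least one genotyped control")
    p = controls.n_c_alleles / (2 * n)
    if p == 0.0 or p == 1.0:
        logger.info("monomorphic controls; HWE p set to 1 by convention")
        return 1.0
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    observed = (controls.n_cc, controls.n_ct, controls.n_tt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return float(stats.chi2.sf(chi2, df=1))


def annotate_hwe(studies: Sequence[StudyRecord]) -> None:
    """Compute and stamp ``hwe_p`` on every study record in place."""
    for s in studies:
        s.hwe_p = hwe_test(s.controls)


def compute_effects(
    studies: Sequence[StudyRecord], model: str, correction: bool = True
) -> list[EffectEstimate]:
    """Per-study effect estimates under one genetic model.

    Studies whose 2x2 table is degenerate are skipped (with a warning
    from :func:`odds_ratio`).
    """
    effects = []
    for s in studies:
        est = odds_ratio(
            contrast(s.cases, s.controls, model),
            study_id=s.study_id,
            model=model,
            correction=correction,
        )
        if est is not None:
            effects.append(est)
    return effects
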