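"""Fixed-effect and DerSimonian-Laird random-effects pooling.

Per-study log odds ratios are combined by inverse-variance weighting.
Heterogeneity is summarized by Cochran's Q (chi-square with k-1 df
reference), I-squared (the percentage of total variation attributable to
between-study variance) and the DerSimonian-Laird moment estimator of
the between-study variance tau-squared.  Model selection follows the
usual screening rule: the random-effects result is reported as primary
when the Q test has p < 0.1 or I-squared exceeds 50%, the fixed-effect
result otherwise; both are always computed.

Sensitivity analyses: per-stratum subgroup pooling, leave-one-out
re-pooling, and re-pooling restricted to studies whose controls pass the
Hardy-Weinberg check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_models import compute_effects
from .errors import UsageError
from .study_data import EffectEstimate, StudyRecord

logger = logging.getLogger("metamr.meta_engine")

#: Default heterogeneity screening thresholds.
Q_P_THRESHOLD = 0.1
I2_THRESHOLD = 50.0


@dataclass(frozen=True)
class PooledResult:
    """A pooled log odds ratio with heterogeneity diagnostics."""

    model: str
    k: int
    pooled_log_or: float
    se: float
    ci_low: float  # odds-ratio scale
    ci_high: float  # odds-ratio scale
    p_value: float
    Q: float
    q_p: float
    i_squared: float  # percent, in [0, 100]
    tau_squared: float
    effects_model: str  # "fixed" | "random"
    weights: tuple[float, ...] = field(default=(), repr=False)
    study_ids: tuple[str, ...] = field(default=(), repr=False)

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "or": self.pooled_or,
            "log_or": self.pooled_log_or,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "Q": self.Q,
            "q_p": self.q_p,
            "i_squared": self.i_squared,
            "tau_squared": self.tau_squared,
            "effects_model": self.effects_model,
        }


def _as_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise UsageError("cannot pool an empty collection of effect estimates")
    theta = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        raise UsageError("all standard errors must be positive")
    return theta, se


def _finish(
    model: str,
    effects: Sequence[EffectEstimate],
    pooled: float,
    pooled_se: float,
    weights: np.ndarray,
    Q: float,
    q_p: float,
    i2: float,
    tau2: float,
    effects_model: str,
) -> PooledResult:
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.96 * pooled_se
    w = weights / weights.sum()
    return PooledResult(
        model=model,
        k=len(effects),
        pooled_log_or=float(pooled),
        se=float(pooled_se),
        ci_low=float(math.exp(pooled - half)),
        ci_high=float(math.exp(pooled + half)),
        p_value=float(p),
        Q=float(Q),
        q_p=float(q_p),
        i_squared=float(i2),
        tau_squared=float(tau2),
        effects_model=effects_model,
        weights=tuple(float(x) for x in w),
        study_ids=tuple(e.study_id for e in effects),
    )


def heterogeneity(effects: Sequence[EffectEstimate]) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value, and I-squared (percent).

    A single study has no between-study information: (0, 1, 0) by
    convention.  I-squared = max(0, (Q - (k-1))/Q) * 100.
    """
    theta, se = _as_arrays(effects)
    k = len(theta)
    if k == 1:
        return 0.0, 1.0, 0.0
    w = 1.0 / se**2
    theta_f = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_f) ** 2))
    q_p = float(stats.chi2.sf(Q, df=k - 1))
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return Q, q_p, i2


def dl_tau_squared(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimate of between-study variance."""
    theta, se = _as_arrays(effects)
    k = len(theta)
    if k < 2:
        return 0.0
    w = 1.0 / se**2
    Q, _, _ = heterogeneity(effects)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / denom)


def pool_fixed(effects: Sequence[EffectEstimate], model: str | None = None) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    theta, se = _as_arrays(effects)
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    Q, q_p, i2 = heterogeneity(effects)
    return _finish(
        model or effects[0].model, effects, pooled, pooled_se, w, Q, q_p, i2, 0.0, "fixed"
    )


def pool_random(effects: Sequence[EffectEstimate], model: str | None = None) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    With tau-squared truncated at zero (Q <= k-1) the weights reduce to
    the fixed-effect ones and the result equals :func:`pool_fixed`.
    """
    theta, se = _as_arrays(effects)
    tau2 = dl_tau_squared(effects)
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    Q, q_p, i2 = heterogeneity(effects)
    return _finish(
        model or effects[0].model, effects, pooled, pooled_se, w_star, Q, q_p, i2, tau2, "random"
    )


def select_model(
    q_p: float,
    i_squared: float,
    q_p_threshold: float = Q_P_THRESHOLD,
    i2_threshold: float = I2_THRESHOLD,
) -> str:
    """Heterogeneity screening rule: 'random' iff q_p < 0.1 or I2 > 50."""
    return "random" if (q_p < q_p_threshold or i_squared > i2_threshold) else "fixed"


@dataclass(frozen=True)
class ModelAnalysis:
    """Fixed and random pooled results for one genetic model, plus the pick."""

    fixed: PooledResult
    random: PooledResult
    selected: str  # "fixed" | "random"

    @property
    def primary(self) -> PooledResult:
        return self.random if self.selected == "random" else self.fixed


def pool_auto(
    effects: Sequence[EffectEstimate],
    model: str | None = None,
    q_p_threshold: float = Q_P_THRESHOLD,
    i2_threshold: float = I2_THRESHOLD,
) -> ModelAnalysis:
    """Pool under both effects models and apply the selection rule."""
    fixed = pool_fixed(effects, model=model)
    random = pool_random(effects, model=model)
    selected = select_model(fixed.q_p, fixed.i_squared, q_p_threshold, i2_threshold)
    return ModelAnalysis(fixed=fixed, random=random, selected=selected)


def subgroup_analysis(
    studies: Sequence[StudyRecord], model: str, stratifier: str
) -> dict[str, ModelAnalysis]:
    """Pool separately within each level of ``stratifier``.

    ``stratifier`` is 'ethnicity' or 'control_source'.  Strata with no
    estimable study are omitted.
    """
    if stratifier not in ("ethnicity", "control_source"):
        raise UsageError(f"unknown stratifier {stratifier!r}")
    out: dict[str, ModelAnalysis] = {}
    levels = sorted({getattr(s, stratifier) for s in studies})
    for level in levels:
        subset = [s for s in studies if getattr(s, stratifier) == level]
        effects = compute_effects(subset, model)
        if not effects:
            logger.warning("stratum %s=%s has no estimable study; omitted", stratifier, level)
            continue
        out[level] = pool_auto(effects, model=model)
    return out


def leave_one_out(
    studies: Sequence[StudyRecord], model: str
) -> list[tuple[str, PooledResult]]:
    """Sequential-removal sensitivity analysis.

    Row i re-runs the full pooling (including model selection) with
    study i excluded.
    """
    if len(studies) < 2:
        raise UsageError("leave-one-out needs at least two studies")
    rows: list[tuple[str, PooledResult]] = []
    for omit in studies:
        subset = [s for s in studies if s.study_id != omit.study_id]
        effects = compute_effects(subset, model)
        if not effects:
            continue
        rows.append((omit.study_id, pool_auto(effects, model=model).primary))
    return rows


def hwe_exclusion(
    studies: Sequence[StudyRecord], model: str, alpha: float = 0.05
) -> PooledResult:
    """Re-pool using only studies whose controls pass the HWE check.

    Studies must already carry ``hwe_p`` (see
    :func:`metamr.effect_models.annotate_hwe`).
    """
    kept = [s for s in studies if s.hwe_p is not None and s.hwe_p >= alpha]
    if not kept:
        raise UsageError("no studies with controls in HWE at the given alpha")
    n_dropped = len(studies) - len(kept)
    if n_dropped:
        logger.info("HWE sensitivity: excluding %d of %d studies", n_dropped, len(studies))
    effects = compute_effects(kept, model)
    if not effects:
        raise UsageError("no estimable studies remain after HWE exclusion")
    return pool_auto(effects, model=model).primary


def forest_table(effects: Sequence[EffectEstimate], pooled: PooledResult):
    """Per-study OR/CI/weight rows plus the pooled row, for forest plots."""
    import pandas as pd

    rows = []
    for e, w in zip(effects, pooled.weights):
        half = 1.96 * e.se
        rows.append(
            {
                "study_id": e.study_id,
                "or": math.exp(e.log_or),
                "ci_low": math.exp(e.log_or - half),
                "ci_high": math.exp(e.log_or + half),
                "weight_pct": 100.0 * w,
            }
        )
    rows.append(
        {
            "study_id": f"pooled ({pooled.effects_model})",
            "or": pooled.pooled_or,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
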