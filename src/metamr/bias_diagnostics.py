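"""Small-study (publication) bias diagnostics.

Egger's regression test fits ordinary least squares of the standardized
effect (log-OR / SE) on precision (1 / SE); a non-zero intercept signals
funnel asymmetry.  Begg and Mazumdar's test rank-correlates the
variance-standardized deviates from the fixed-effect pooled estimate
with the study variances (Kendall's tau with a continuity-corrected
normal approximation).  Both are reported with two-sided p-values and
the conventional alpha = 0.05 labeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import UsageError
from .meta_engine import pool_fixed
from .study_data import EffectEstimate

logger = logging.getLogger("metamr.bias_diagnostics")


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # "egger" | "begg"
    statistic: float  # t for Egger, z for Begg
    p_value: float
    intercept: float | None = None  # Egger only
    intercept_se: float | None = None  # Egger only
    tau: float | None = None  # Begg only: Kendall's tau

    def to_dict(self) -> dict:
        d = {"method": self.method, "statistic": self.statistic, "p_value": self.p_value}
        if self.method == "egger":
            d["intercept"] = self.intercept
            d["intercept_se"] = self.intercept_se
        else:
            d["kendall_tau"] = self.tau
        return d


def egger_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression asymmetry test.

    OLS of y_i = theta_i / se_i on x_i = 1 / se_i; the test statistic is
    intercept / SE(intercept) referred to a t distribution with k - 2
    degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise UsageError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in effects], dtype=float)
    theta = np.array([e.log_or for e in effects], dtype=float)
    x = 1.0 / se
    y = theta / se
    if np.allclose(x, x[0]) or np.allclose(y - y.mean(), 0):
        logger.warning("degenerate Egger fit (no spread in precision or effect); p set to 1")
        return BiasTestResult("egger", 0.0, 1.0, intercept=0.0, intercept_se=float("inf"))
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    if intercept_se <= 1e-12:
        # zero-residual fit: the line passes exactly through every point
        logger.warning("exact Egger fit; intercept tested against a zero SE")
        p = 1.0 if abs(intercept) <= 1e-12 else 0.0
        return BiasTestResult(
            "egger", 0.0 if p == 1.0 else math.inf, p,
            intercept=intercept, intercept_se=intercept_se,
        )
    t = intercept / intercept_se
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 2))
    return BiasTestResult("egger", float(t), p, intercept=intercept, intercept_se=intercept_se)


def _kendall_s_and_tau(u: np.ndarray, v: np.ndarray) -> tuple[int, float, int, float]:
    """Kendall score S = (#concordant - #discordant), tau, and its null variance.

    The variance uses the standard tie adjustment (subtracting the tied-
    group terms for each variable), which reduces to n(n-1)(2n+5)/18 when
    everything is distinct.
    """
    n = len(u)
    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    iu = np.triu_indices(n, k=1)
    prod = du[iu] * dv[iu]
    s = int(np.sum(prod))
    n_pairs = n * (n - 1) // 2
    tau = s / n_pairs

    def tie_term(x: np.ndarray) -> float:
        _, counts = np.unique(x, return_counts=True)
        return float(sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1))

    var = (n * (n - 1) * (2 * n + 5) - tie_term(u) - tie_term(v)) / 18.0
    return s, tau, n_pairs, var


def begg_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar adjusted rank-correlation test.

    Deviates u_i = (theta_i - theta_F) / sqrt(se_i^2 - 1/sum(w)) are rank-
    correlated with the variances se_i^2; the conditional variance term
    removes the dependence of each deviate on the pooled estimate.  A
    continuity correction of 1 is applied to |S| in the normal
    approximation.
    """
    k = len(effects)
    if k < 3:
        raise UsageError("Begg's test needs at least 3 studies")
    se = np.array([e.se for e in effects], dtype=float)
    theta = np.array([e.log_or for e in effects], dtype=float)
    fixed = pool_fixed(effects)
    v = se**2
    cond_var = v - 1.0 / np.sum(1.0 / v)
    # cond_var > 0 for k >= 2 unless a study carries all the weight
    cond_var = np.maximum(cond_var, np.finfo(float).tiny)
    u = (theta - fixed.pooled_log_or) / np.sqrt(cond_var)
    s, tau, _, var = _kendall_s_and_tau(u, v)
    if var <= 0:
        logger.warning("degenerate Begg test (all ranks tied); p set to 1")
        return BiasTestResult("begg", 0.0, 1.0, tau=tau)
    z = max(abs(s) - 1, 0) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(z))
    return BiasTestResult("begg", float(z), min(p, 1.0), tau=float(tau))


def funnel_data(effects: Sequence[EffectEstimate], n_grid: int = 50) -> pd.DataFrame:
    """Funnel-plot coordinates: per-study points plus pseudo-95% bounds.

    Rows with ``kind == 'study'`` hold (log_or, se) points ranked by
    precision (rank 1 = most precise, plotted at the top of an inverted
    SE axis); rows with ``kind == 'bound'`` trace the fixed-effect
    pooled estimate +/- 1.96 * se over an SE grid.
    """
    if len(effects) < 1:
        raise UsageError("funnel data needs at least one study")
    se = np.array([e.se for e in effects], dtype=float)
    theta = np.array([e.log_or for e in effects], dtype=float)
    ranks = stats.rankdata(se, method="ordinal").astype(int)
    rows = [
        {
            "kind": "study",
            "study_id": e.study_id,
            "log_or": float(t),
            "se": float(s),
            "precision_rank": int(r),
            "lower": np.nan,
            "upper": np.nan,
        }
        for e, t, s, r in zip(effects, theta, se, ranks)
    ]
    pooled = pool_fixed(effects).pooled_log_or if len(effects) > 1 else float(theta[0])
    grid = np.linspace(0.0, float(se.max()) * 1.05, n_grid)
    for g in grid:
        rows.append(
            {
                "kind": "bound",
                "study_id": "",
                "log_or": pooled,
                "se": float(g),
                "precision_rank": 0,
                "lower": pooled - 1.96 * g,
                "upper": pooled + 1.96 * g,
            }
        )
    return pd.DataFrame(rows)
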