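"""Rubin's-rules pooling and simulation performance measures.

Scalar pooling across M imputed datasets: point estimate Qbar = mean,
within-imputation variance Wbar = mean of the per-imputation variances,
between-imputation variance B = sample variance of the estimates, total
variance T = Wbar + (1 + 1/M) B.  Confidence intervals use the
Barnard-Rubin small-sample degrees of freedom when a complete-data
degrees-of-freedom value is supplied, else the classical large-sample
formula.

Performance across simulation replicates: bias, empirical SD,
standardized bias (bias / empirical SD), average model-based SE, and
coverage of the 95% interval, each with its Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PooledEstimate", "rubins_rules", "evaluate"]


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    se: float
    ci: tuple[float, float]
    m: int


def rubins_rules(
    estimates, variances, df_complete: float | None = None, level: float = 0.95
) -> PooledEstimate:
    """Pool M scalar estimates and their variances.

    Parameters
    ----------
    estimates, variances : sequence of float, length M >= 2
        Per-imputation point estimates and squared standard errors.
    df_complete : float, optional
        Complete-data degrees of freedom; switches the interval to the
        Barnard-Rubin adjusted degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    if u.size != m or np.any(u < 0):
        raise ValueError("variances must match estimates and be nonnegative")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    if b < 1e-14 * max(1.0, qbar * qbar, wbar):  # numerically identical estimates
        b = 0.0
    t = wbar + (1.0 + 1.0 / m) * b

    if b == 0.0 or t == 0.0:
        df = math.inf
    else:
        r = (1.0 + 1.0 / m) * b
        df_large = (m - 1) * (1.0 + wbar / r) ** 2
        if df_complete is None:
            df = df_large
        else:
            lam = r / t
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
            df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
    se = math.sqrt(t)
    crit = stats.norm.ppf(0.5 + level / 2) if math.isinf(df) else stats.t.ppf(0.5 + level / 2, df)
    return PooledEstimate(
        estimate=qbar,
        within_var=wbar,
        between_var=b,
        total_var=t,
        df=df,
        se=se,
        ci=(qbar - crit * se, qbar + crit * se),
        m=m,
    )


def evaluate(results: pd.DataFrame, truth: float) -> dict[str, float]:
    """Performance of one estimand across simulation replicates.

    ``results`` needs columns ``est``, ``se``, ``lo``, ``hi`` (one row
    per replicate).  Returns bias, empirical SD, standardized bias,
    average model SE, coverage and their Monte-Carlo SEs.  A degenerate
    zero empirical SD with nonzero bias yields an infinite standardized
    bias (flagged, not masked).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicates to evaluate performance")
    est = results["est"].to_numpy(dtype=float)
    n = est.size
    bias = float(est.mean() - truth)
    sd = float(est.std(ddof=1))
    if sd == 0.0:
        std_bias = 0.0 if bias == 0.0 else math.copysign(math.inf, bias)
    else:
        std_bias = bias / sd
    covered = ((results["lo"] <= truth) & (truth <= results["hi"])).to_numpy(dtype=float)
    coverage = float(covered.mean())
    avg_se = float(results["se"].mean())
    return {
        "n_replicates": n,
        "bias": bias,
        "empirical_sd": sd,
        "std_bias": std_bias,
        "avg_model_se": avg_se,
        "coverage": coverage,
        "mcse_bias": sd / math.sqrt(n),
        "mcse_coverage": math.sqrt(coverage * (1.0 - coverage) / n),
    }
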