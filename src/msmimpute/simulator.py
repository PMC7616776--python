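"""Data-generating mechanism for the illness-death Markov model.

Three states: 0 = transplant (initial), 1 = aGvHD (intermediate),
2 = relapse/death (absorbing).  Each transition intensity has a Weibull
proportional-hazards form on the clock-forward (time-since-transplant)
scale,

    alpha_ab(t; z) = (shape/scale) * (t/scale)^(shape-1) * exp(beta' z),

so the cumulative intensity is A_ab(t; z) = (t/scale)^shape * exp(beta' z).
Times are in days with origin at transplant.

Cohort layout (one row per patient):

    id, z1, z2, aghd_status, aghd_time, rd_status, rd_time,
    true_aghd_time, true_rd_time, aghd_time_missing, rd_time_missing

Coding conventions for the observed columns: a patient without aGvHD
carries the relapse/death (or censoring) time in ``aghd_time`` with
``aghd_status = 0``; a censored patient carries the censoring time in both
time columns.  Censored times are never treated as missing.  ``true_*``
columns retain the pre-masking values for performance evaluation only and
must never feed an estimation routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "id",
    "z1",
    "z2",
    "aghd_status",
    "aghd_time",
    "rd_status",
    "rd_time",
    "true_aghd_time",
    "true_rd_time",
    "aghd_time_missing",
    "rd_time_missing",
]


@dataclass(frozen=True)
class WeibullPHSpec:
    """One transition's Weibull proportional-hazards intensity.

    Parameters
    ----------
    shape : float
        Weibull shape; the printed exponent on (t/scale) in the intensity
        is ``shape - 1``.
    scale : float
        Weibull scale in days.
    coefficients : tuple of float
        Log hazard ratios, one per covariate used by this transition.
    """

    shape: float
    scale: float
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def linear_predictor(self, z: Sequence[float]) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        beta = np.asarray(self.coefficients, dtype=float)
        if z.shape[-1] != beta.size:
            raise ValueError(
                f"covariate vector of length {z.shape[-1]} does not match "
                f"{beta.size} coefficient(s)"
            )
        return z @ beta


# Defaults: transition 0->1 (transplant to aGvHD) depends on z1 only,
# 0->2 (transplant to relapse/death) on z1 only, and 1->2 (aGvHD to
# relapse/death) on (z1, z2).
DEFAULT_SPEC01 = WeibullPHSpec(shape=1.5, scale=36.0, coefficients=(-0.8,))
DEFAULT_SPEC02 = WeibullPHSpec(shape=0.9, scale=120.0, coefficients=(1.2,))
DEFAULT_SPEC12 = WeibullPHSpec(shape=0.8, scale=160.0, coefficients=(1.2, -1.0))


@dataclass(frozen=True)
class DGMConfig:
    """Full configuration of the data-generating mechanism.

    Defaults encode the study conditions: z1 ~ Bernoulli(0.2) (in relapse
    at transplant), z2 ~ Bernoulli(0.45) (double cord transplant),
    administrative censoring Uniform(365, 1825) days, cohorts of 500.
    """

    spec01: WeibullPHSpec = DEFAULT_SPEC01
    spec02: WeibullPHSpec = DEFAULT_SPEC02
    spec12: WeibullPHSpec = DEFAULT_SPEC12
    p_z1: float = 0.2
    p_z2: float = 0.45
    censor_min: float = 365.0
    censor_max: float = 1825.0
    n_patients: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_z1 <= 1.0 and 0.0 <= self.p_z2 <= 1.0):
            raise ValueError("covariate prevalences must lie in [0, 1]")
        if not (0.0 < self.censor_min <= self.censor_max):
            raise ValueError("require 0 < censor_min <= censor_max")
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")


def cumulative_intensity(spec: WeibullPHSpec, t, z) -> np.ndarray | float:
    """Cumulative transition intensity A(t; z) = (t/scale)^shape * exp(beta'z)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    lp = spec.linear_predictor(z)
    out = (t_arr / spec.scale) ** spec.shape * np.exp(lp)
    if np.isscalar(t) and out.size == 1:
        return float(out.reshape(-1)[0])
    return out


def inverse_cumulative_intensity(spec: WeibullPHSpec, target, z) -> np.ndarray | float:
    """Solve A(t; z) = target for t: t = scale * (target / exp(beta'z))^(1/shape)."""
    tg = np.asarray(target, dtype=float)
    if np.any(tg < 0):
        raise ValueError("target cumulative intensity must be nonnegative")
    lp = spec.linear_predictor(z)
    out = spec.scale * (tg / np.exp(lp)) ** (1.0 / spec.shape)
    if np.isscalar(target) and out.size == 1:
        return float(out.reshape(-1)[0])
    return out


def _intensity(spec: WeibullPHSpec, t, z) -> np.ndarray:
    """Instantaneous intensity alpha(t; z); infinite at t=0 when shape < 1."""
    t = np.asarray(t, dtype=float)
    lp = spec.linear_predictor(z)
    with np.errstate(divide="ignore"):
        base = (spec.shape / spec.scale) * (t / spec.scale) ** (spec.shape - 1.0)
    return base * np.exp(lp)


def simulate_paths(config: DGMConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw complete (uncensored) event histories for every patient.

    The two cause-specific exit times from state 0 are drawn by inverting
    their cumulative intensities at independent standard-exponential
    deviates; the earlier one realises.  This is distributionally
    identical to drawing the exit time from the total hazard and then the
    destination from the relative intensities.  A patient who enters
    aGvHD at t1 gets a 1->2 time on the same clock-forward scale by
    solving A12(t2) - A12(t1) = Exp(1).

    Returns columns z1, z2, via_aghd, t1 (aGvHD time, NaN on the direct
    path) and t2 (relapse/death time).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_patients
    z1 = (rng.random(n) < config.p_z1).astype(int)
    z2 = (rng.random(n) < config.p_z2).astype(int)
    z01 = z1[:, None].astype(float)
    z12 = np.column_stack([z1, z2]).astype(float)

    e01 = rng.exponential(size=n)
    e02 = rng.exponential(size=n)
    t01 = inverse_cumulative_intensity(config.spec01, e01, z01)
    t02 = inverse_cumulative_intensity(config.spec02, e02, z01)

    via_aghd = t01 < t02
    e12 = rng.exponential(size=n)
    a12_at_t1 = cumulative_intensity(config.spec12, np.where(via_aghd, t01, 0.0), z12)
    t2_after = inverse_cumulative_intensity(config.spec12, a12_at_t1 + e12, z12)
    t2 = np.where(via_aghd, t2_after, t02)
    return pd.DataFrame(
        {
            "z1": z1,
            "z2": z2,
            "via_aghd": via_aghd,
            "t1": np.where(via_aghd, t01, np.nan),
            "t2": t2,
        }
    )


def simulate_cohort(config: DGMConfig) -> pd.DataFrame:
    """Simulate a complete cohort and apply independent right-censoring.

    Event histories come from :func:`simulate_paths`; censoring
    C ~ Uniform(censor_min, censor_max) is independent of the event
    times and the state occupied.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS).astype(
            {"aghd_time_missing": bool, "rd_time_missing": bool}
        )

    paths = simulate_paths(config, rng)
    z1 = paths["z1"].to_numpy()
    z2 = paths["z2"].to_numpy()
    via_aghd = paths["via_aghd"].to_numpy()
    t1_latent = np.where(via_aghd, paths["t1"].to_numpy(), np.inf)
    t2_latent = paths["t2"].to_numpy()

    censor = rng.uniform(config.censor_min, config.censor_max, size=n)

    aghd_status = (via_aghd & (t1_latent <= censor)).astype(int)
    rd_status = (t2_latent <= censor).astype(int)

    rd_time = np.where(rd_status == 1, t2_latent, censor)
    # Patient with aGvHD keeps the aGvHD time; without aGvHD the column
    # carries the relapse/death or censoring time.
    aghd_time = np.where(aghd_status == 1, t1_latent, rd_time)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "z1": z1,
            "z2": z2,
            "aghd_status": aghd_status,
            "aghd_time": aghd_time,
            "rd_status": rd_status,
            "rd_time": rd_time,
            "true_aghd_time": aghd_time,
            "true_rd_time": rd_time,
            "aghd_time_missing": np.zeros(n, dtype=bool),
            "rd_time_missing": np.zeros(n, dtype=bool),
        }
    )


def state_occupancy_weibull(
    spec01: WeibullPHSpec,
    spec02: WeibullPHSpec,
    spec12: WeibullPHSpec,
    z: Sequence[float],
    grid: np.ndarray,
) -> pd.DataFrame:
    """State occupation probabilities under Weibull PH intensities.

    For a patient starting in state 0 at t=0 with covariates z = (z1, z2)
    (transitions from state 0 use z1 only; 1->2 uses both),

        P0(t) = exp(-A01(t) - A02(t))
        P1(t) = int_0^t P0(u) alpha01(u) exp(-(A12(t) - A12(u))) du
        P2(t) = 1 - P0(t) - P1(t).

    P1 is advanced recursively over the grid,

        P1(t_{k+1}) = P1(t_k) e^{-dA12} + (increment over (t_k, t_{k+1}]),

    with the increment integrated by the trapezoidal rule, so the cost is
    linear in the grid size.  The grid must start at 0 and increase
    strictly; a fine grid (e.g. 0.1-day steps) controls the O(step^2)
    quadrature error.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must start at 0 and be strictly increasing")
    z = np.asarray(z, dtype=float)
    z0 = z[:1]  # transitions from transplant use z1 only
    a01 = np.asarray(cumulative_intensity(spec01, grid, z0)).reshape(-1)
    a02 = np.asarray(cumulative_intensity(spec02, grid, z0)).reshape(-1)
    a12 = np.asarray(cumulative_intensity(spec12, grid, z)).reshape(-1)
    p0 = np.exp(-a01 - a02)
    f = p0 * np.asarray(_intensity(spec01, grid, z0)).reshape(-1)
    # integrable singularity at t=0 when shape01 < 1; the first trapezoid
    # cell then underestimates by O(h^shape), negligible on a fine grid
    f[grid == 0.0] = 0.0
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("integrand not finite on grid")

    p1 = np.zeros_like(grid)
    for k in range(len(grid) - 1):
        da12 = a12[k + 1] - a12[k]
        h = grid[k + 1] - grid[k]
        # trapezoid of P0*alpha01 with survival weighting at each endpoint
        inc = 0.5 * h * (f[k] * np.exp(-da12) + f[k + 1])
        p1[k + 1] = p1[k] * np.exp(-da12) + inc
    p2 = 1.0 - p0 - p1
    return pd.DataFrame({"time": grid, "P0": p0, "P1": p1, "P2": p2, "source": "true"})


def true_state_probs(config: DGMConfig, z: Sequence[float], grid: np.ndarray) -> pd.DataFrame:
    """True state occupation probabilities under the configured DGM."""
    path = state_occupancy_weibull(config.spec01, config.spec02, config.spec12, z, grid)
    resid = np.abs(path[["P0", "P1", "P2"]].sum(axis=1) - 1.0).max()
    if resid > 1e-6:
        raise FloatingPointError(f"probability conservation violated ({resid:.2e})")
    return path
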