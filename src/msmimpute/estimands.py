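"""State occupation probabilities and restricted expected length of stay.

The transition probability matrix of a Markov multi-state process is the
product integral of the cumulative transition intensities,

    P(s, t) = prod_{(s,t]} (I + dA(u)),  alpha_aa = -sum_{b != a} alpha_ab.

With Breslow increments from Cox fits this is the covariate-conditional
Aalen-Johansen estimator evaluated on the pooled event-time grid; with
Weibull fits the same occupancy formulas are evaluated in closed form /
by quadrature on a fixed fine grid (0.1-day steps by default).

Restricted expected length of stay (RELOS) in state b up to horizon t is
e_b(t) = int_0^t P_b(u) du, estimated by the left-endpoint step-function
sum  sum_m P_b(t_m) (t_{m+1} - t_m)  with the last interval closed at the
horizon.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .msm_fit import CoxFit, WeibullFit, fit_cox, to_transition_datasets
from .simulator import WeibullPHSpec, state_occupancy_weibull

logger = logging.getLogger(__name__)

__all__ = [
    "aalen_johansen",
    "state_probs_weibull",
    "relos",
    "bootstrap_se_relos",
    "delta_se_relos",
]

STATES = ("P0", "P1", "P2")


def _increments(fit: CoxFit, z: np.ndarray, horizon: float) -> pd.DataFrame:
    """Covariate-specific cumulative-intensity increments up to the horizon."""
    lp = float(np.asarray(z, dtype=float)[: len(fit.covariates)] @ fit.beta)
    b = fit.baseline
    keep = b["time"].to_numpy() <= horizon
    return pd.DataFrame(
        {"time": b["time"].to_numpy()[keep], "dA": b["increment"].to_numpy()[keep] * np.exp(lp)}
    )


def aalen_johansen(fits: dict[str, CoxFit], z, horizon: float = 730.0) -> pd.DataFrame:
    """State occupation probabilities from three Cox fits by product integration.

    ``fits`` maps "01", "02", "12" to their CoxFit.  The grid is the
    pooled set of event times across the three transitions up to the
    horizon.  Any product-integral step with a negative diagonal (an
    increment exceeding 1) is reported via a warning, never silently
    clipped.
    """
    z = np.asarray(z, dtype=float)
    inc = {k: _increments(f, z, horizon) for k, f in fits.items()}
    grid = np.unique(np.concatenate([df["time"].to_numpy() for df in inc.values()]))
    lookup = {
        k: dict(zip(df["time"].to_numpy(), df["dA"].to_numpy())) for k, df in inc.items()
    }
    P = np.eye(3)
    times = [0.0]
    probs = [P[0].copy()]
    bad_steps: list[float] = []
    for t in grid:
        dA = np.zeros((3, 3))
        dA[0, 1] = lookup["01"].get(t, 0.0)
        dA[0, 2] = lookup["02"].get(t, 0.0)
        dA[1, 2] = lookup["12"].get(t, 0.0)
        dA[0, 0] = -(dA[0, 1] + dA[0, 2])
        dA[1, 1] = -dA[1, 2]
        if np.any(1.0 + np.diag(dA) < 0.0):
            bad_steps.append(float(t))
        P = P @ (np.eye(3) + dA)
        times.append(float(t))
        probs.append(P[0].copy())
    if bad_steps:
        warnings.warn(
            f"{len(bad_steps)} product-integral step(s) have a negative diagonal "
            f"(increment > 1; first at t={bad_steps[0]:.4g}); occupation "
            "probabilities may leave [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
    probs = np.asarray(probs)
    out = pd.DataFrame(
        {"time": times, "P0": probs[:, 0], "P1": probs[:, 1], "P2": probs[:, 2]}
    )
    out["source"] = "cox"
    return out


def state_probs_weibull(
    fits: dict[str, WeibullFit], z, horizon: float = 730.0, step: float = 0.1
) -> pd.DataFrame:
    """Occupancy from Weibull fits on a fixed fine grid (default 0.1 days)."""
    for k, f in fits.items():
        if not f.converged:
            raise RuntimeError(f"Weibull fit for transition {k} did not converge")
    specs = {
        k: WeibullPHSpec(shape=f.shape, scale=f.scale, coefficients=tuple(f.beta))
        for k, f in fits.items()
    }
    grid = np.arange(0.0, horizon + step / 2.0, step)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    path = state_occupancy_weibull(specs["01"], specs["02"], specs["12"], z, grid)
    path["source"] = "weibull"
    return path


def relos(path: pd.DataFrame, horizon: float = 730.0) -> dict[str, float]:
    """Left-endpoint step-function integral of each occupancy column.

    e_b = sum_m P_b(t_m) (t_{m+1} - t_m) over grid times below the
    horizon, with the final interval closed at the horizon.
    """
    t = path["time"].to_numpy(dtype=float)
    if t[0] != 0.0:
        raise ValueError("occupancy grid must start at time 0")
    if horizon < t[0]:
        raise ValueError("horizon precedes the first grid point")
    keep = t < horizon
    tt = np.append(t[keep], horizon)
    gaps = np.diff(tt)
    out = {}
    for s in STATES:
        p = path[s].to_numpy(dtype=float)[keep]
        out[s.replace("P", "e")] = float(p @ gaps)
    return out


def bootstrap_se_relos(
    cohort: pd.DataFrame,
    z,
    horizon: float = 730.0,
    B: int = 50,
    seed: int = 0,
    on_violation: str = "error",
) -> dict[str, float]:
    """Nonparametric bootstrap SE of RELOS under Cox fits.

    Patients are resampled with replacement; the three Cox models are
    refitted and RELOS recomputed per replicate.  Fails loudly when more
    than 20% of bootstrap refits fail.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    reps: list[dict[str, float]] = []
    failures = 0
    with warnings.catch_warnings():
        # duplicated patients create large tied increments in nearly
        # every resample; per-resample reports carry no information here
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            boot = cohort.iloc[idx].reset_index(drop=True)
            boot["id"] = np.arange(n)
            try:
                tds = to_transition_datasets(boot, on_violation=on_violation)
                fits = {k: fit_cox(td) for k, td in tds.items()}
                path = aalen_johansen(fits, z, horizon)
                reps.append(relos(path, horizon))
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
    if failures > 0.2 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    arr = {k: np.array([r[k] for r in reps]) for k in ("e0", "e1", "e2")}
    return {k: float(v.std(ddof=1)) for k, v in arr.items()}


def _stack_params(fits: dict[str, WeibullFit]) -> tuple[np.ndarray, np.ndarray, list[int]]:
    blocks, sizes = [], []
    theta = []
    for k in ("01", "02", "12"):
        f = fits[k]
        theta.extend([np.log(f.shape), np.log(f.scale), *f.beta])
        blocks.append(f.vcov)
        sizes.append(2 + len(f.beta))
    V = np.zeros((sum(sizes), sum(sizes)))
    o = 0
    for b, s in zip(blocks, sizes):
        V[o : o + s, o : o + s] = b
        o += s
    return np.asarray(theta), V, sizes


def delta_se_relos(
    fits: dict[str, WeibullFit], z, horizon: float = 730.0, step: float = 0.1,
    rel_step: float = 1e-5,
) -> dict[str, float]:
    """Delta-method SE of RELOS for Weibull fits.

    RELOS is differentiated numerically (central differences, relative
    step 1e-5) with respect to the stacked parameter vector
    (log shape, log scale, beta) x 3 transitions, and sandwiched with the
    block-diagonal variance-covariance of the three fits.
    """
    theta0, V, sizes = _stack_params(fits)
    if not np.all(np.isfinite(V)):
        raise ValueError("variance-covariance unavailable for at least one fit")

    def relos_at(theta: np.ndarray) -> np.ndarray:
        specs = []
        o = 0
        for s in sizes:
            block = theta[o : o + s]
            specs.append(
                WeibullPHSpec(
                    shape=float(np.exp(block[0])),
                    scale=float(np.exp(block[1])),
                    coefficients=tuple(block[2:]),
                )
            )
            o += s
        grid = np.arange(0.0, horizon + step / 2.0, step)
        path = state_occupancy_weibull(specs[0], specs[1], specs[2], z, grid)
        r = relos(path, horizon)
        return np.array([r["e0"], r["e1"], r["e2"]])

    n_par = theta0.size
    grad = np.zeros((3, n_par))
    for j in range(n_par):
        h = rel_step * max(1.0, abs(theta0[j]))
        up = theta0.copy(); up[j] += h
        dn = theta0.copy(); dn[j] -= h
        grad[:, j] = (relos_at(up) - relos_at(dn)) / (2.0 * h)
    cov = grad @ V @ grad.T
    return {f"e{b}": float(np.sqrt(max(cov[b, b], 0.0))) for b in range(3)}
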