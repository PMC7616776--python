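"""Transition-intensity model fitting for the illness-death model.

All three transitions are modelled on the clock-forward scale (days since
transplant).  The 1->2 transition uses delayed entry: a patient joins its
risk set at the aGvHD time (left truncation).  The Cox fitter maximises
the partial likelihood with Breslow tie handling (imputed times produce
genuine ties) and returns Breslow baseline cumulative-intensity
increments; the Weibull fitter maximises the full likelihood of a
Weibull proportional-hazards intensity with left truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionDataset",
    "CoxFit",
    "WeibullFit",
    "MarkovTestFit",
    "to_transition_datasets",
    "fit_cox",
    "fit_weibull_ph",
    "markov_test",
]


@dataclass
class TransitionDataset:
    """Counting-process rows (entry, exit, status, covariates) for one transition."""

    frame: pd.DataFrame  # columns: id, entry, exit, status, <covariates>
    transition: str  # "01", "02" or "12"
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.frame["entry"] >= self.frame["exit"]).any():
            raise ValueError(f"transition {self.transition}: entry must precede exit")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        f = self.frame
        X = f[list(self.covariates)].to_numpy(dtype=float)
        return (
            f["entry"].to_numpy(dtype=float),
            f["exit"].to_numpy(dtype=float),
            f["status"].to_numpy(dtype=int),
            X,
        )


@dataclass
class CoxFit:
    beta: np.ndarray
    vcov: np.ndarray
    baseline: pd.DataFrame  # columns: time, increment
    covariates: tuple[str, ...]
    converged: bool
    loglik: float
    n_events: int


@dataclass
class WeibullFit:
    shape: float
    scale: float
    beta: np.ndarray
    vcov: np.ndarray  # order: (log shape, log scale, beta...)
    covariates: tuple[str, ...]
    converged: bool
    loglik: float
    n_events: int


@dataclass
class MarkovTestFit:
    gamma: float
    se: float
    ci: tuple[float, float]
    fit: object


def to_transition_datasets(
    cohort: pd.DataFrame, on_violation: str = "error"
) -> dict[str, TransitionDataset]:
    """Expand a completed cohort into the three transition datasets.

    0->1: exit at the aGvHD time, status = aGvHD indicator.
    0->2: censored at aGvHD for patients who transition to state 1;
          otherwise exit at the relapse/death (or censoring) time.
    1->2: delayed entry at the aGvHD time, restricted to aGvHD patients.

    A relapse/death time at or before the aGvHD time in a patient with
    both events violates the model's ordering.  ``on_violation`` selects
    the policy: "error" (default); "drop", which excludes the patient
    from the 1->2 dataset only (such a record carries no valid sojourn
    information; the 0->1 and 0->2 rows are unaffected); or "clip",
    which pushes the relapse/death time just past the aGvHD time.
    Imputation methods that do not enforce event ordering occasionally
    need one of the latter two; counts are logged either way.
    """
    if cohort[["aghd_time", "rd_time"]].isna().any().any():
        raise ValueError("cohort has missing analysis times; impute or filter first")
    c = cohort.copy()
    d1 = c["aghd_status"].to_numpy() == 1
    d2 = c["rd_status"].to_numpy() == 1
    aghd = c["aghd_time"].to_numpy(dtype=float)
    rd = c["rd_time"].to_numpy(dtype=float)

    bad = d1 & (rd <= aghd)
    n_bad = int(bad.sum())
    drop12 = np.zeros(len(c), dtype=bool)
    if n_bad:
        if on_violation == "error":
            raise ValueError(
                f"{n_bad} patient(s) have relapse/death at or before aGvHD; "
                "pass on_violation='drop' or 'clip' to proceed"
            )
        if on_violation == "drop":
            logger.info("dropping %d ordering violation(s) from transition 1->2", n_bad)
            drop12 = bad
        elif on_violation == "clip":
            logger.info("clipping %d ordering violation(s) in transition 1->2", n_bad)
            rd = np.where(bad, aghd + 1e-4, rd)
        else:
            raise ValueError("on_violation must be 'error', 'drop' or 'clip'")

    ids = c["id"].to_numpy()
    z1 = c["z1"].to_numpy(dtype=float)
    z2 = c["z2"].to_numpy(dtype=float)

    td01 = pd.DataFrame(
        {"id": ids, "entry": 0.0, "exit": aghd, "status": d1.astype(int), "z1": z1}
    )
    exit02 = np.where(d1, aghd, rd)
    td02 = pd.DataFrame(
        {
            "id": ids,
            "entry": 0.0,
            "exit": exit02,
            "status": (d2 & ~d1).astype(int),
            "z1": z1,
        }
    )
    in12 = d1 & ~drop12
    td12 = pd.DataFrame(
        {
            "id": ids[in12],
            "entry": aghd[in12],
            "exit": rd[in12],
            "status": d2[in12].astype(int),
            "z1": z1[in12],
            "z2": z2[in12],
        }
    )
    return {
        "01": TransitionDataset(td01, "01", ("z1",)),
        "02": TransitionDataset(td02, "02", ("z1",)),
        "12": TransitionDataset(td12, "12", ("z1", "z2")),
    }


# --------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties, delayed entry)


def _cox_quantities(beta, X, d_k, s_k, at_risk):
    """Log partial likelihood, score and information at beta (Breslow ties)."""
    w = np.exp(X @ beta)
    denom = at_risk @ w  # risk-set sum per distinct event time
    m1 = (at_risk @ (w[:, None] * X)) / denom[:, None]
    ll = float(s_k.sum(axis=0) @ beta - d_k @ np.log(denom))
    score = s_k.sum(axis=0) - (d_k[:, None] * m1).sum(axis=0)
    p = X.shape[1]
    info = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            m2ab = (at_risk @ (w * X[:, a] * X[:, b])) / denom
            val = float((d_k * (m2ab - m1[:, a] * m1[:, b])).sum())
            info[a, b] = info[b, a] = val
    return ll, score, info, denom


def fit_cox(td: TransitionDataset, tol: float = 1e-9, max_iter: int = 50) -> CoxFit:
    """Maximise the Cox partial likelihood with Breslow tie handling.

    Delayed-entry risk sets: subject i is at risk at event time t iff
    entry_i < t <= exit_i.  Returns Breslow baseline increments
    d_k / sum_{R_k} exp(x'beta) at every distinct event time.
    """
    entry, exit_, status, X = td.arrays()
    if status.sum() < 1:
        raise ValueError(f"transition {td.transition}: no events to fit")
    ev = status == 1
    event_times, inv = np.unique(exit_[ev], return_inverse=True)
    d_k = np.bincount(inv).astype(float)
    p = X.shape[1]
    s_k = np.zeros((len(event_times), p))
    np.add.at(s_k, inv, X[ev])
    at_risk = (entry[None, :] < event_times[:, None]) & (exit_[None, :] >= event_times[:, None])
    for j, name in enumerate(td.covariates):
        risk_any = at_risk.any(axis=0)
        if np.ptp(X[risk_any, j]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant in the risk set")

    beta = np.zeros(p)
    ll, score, info, denom = _cox_quantities(beta, X, d_k, s_k, at_risk)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(score)) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new, denom_new = _cox_quantities(cand, X, d_k, s_k, at_risk)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll, score, info, denom = cand, ll_new, score_new, info_new, denom_new
        if np.max(np.abs(beta)) > 50.0:
            logger.warning("transition %s: monotone partial likelihood suspected", td.transition)
            break
    if not converged and np.max(np.abs(score)) < 1e-6 * max(1.0, abs(ll)):
        converged = True
    vcov = np.linalg.inv(info)
    baseline = pd.DataFrame({"time": event_times, "increment": d_k / denom})
    return CoxFit(
        beta=beta,
        vcov=vcov,
        baseline=baseline,
        covariates=td.covariates,
        converged=converged,
        loglik=ll,
        n_events=int(status.sum()),
    )


# --------------------------------------------------------------------------
# Weibull proportional hazards with left truncation


def _weibull_negloglik(params, entry, exit_, status, X):
    log_shape, log_scale = params[0], params[1]
    beta = params[2:]
    shape, scale = np.exp(log_shape), np.exp(log_scale)
    lp = X @ beta
    with np.errstate(over="raise"):
        try:
            dA = ((exit_ / scale) ** shape - (entry / scale) ** shape) * np.exp(lp)
            log_alpha = (
                log_shape - log_scale + (shape - 1.0) * (np.log(exit_) - log_scale) + lp
            )
            ll = float((status * log_alpha).sum() - dA.sum())
        except FloatingPointError:
            return np.inf
    return -ll if np.isfinite(ll) else np.inf


def _weibull_negloglik_grad(params, entry, exit_, status, X):
    """Negative log likelihood and its analytic gradient.

    Parameterisation (log shape, log scale, beta); left truncation enters
    through A(exit) - A(entry).
    """
    f = _weibull_negloglik(params, entry, exit_, status, X)
    if not np.isfinite(f):
        return f, np.zeros_like(params)
    log_shape, log_scale = params[0], params[1]
    beta = params[2:]
    shape, scale = np.exp(log_shape), np.exp(log_scale)
    w = np.exp(X @ beta)
    log_ue = shape * (np.log(exit_) - log_scale)
    ue = np.exp(log_ue)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio_s = np.where(entry > 0.0, np.log(entry) - log_scale, 0.0)
    us = np.where(entry > 0.0, np.exp(shape * log_ratio_s), 0.0)
    # d/d(log shape): events contribute 1 + shape*log(exit/scale); the
    # cumulative part differentiates u = (t/scale)^shape as u*shape*log(t/scale)
    g_a = float(
        (status * (1.0 + log_ue)).sum()
        - (w * (ue * log_ue - us * shape * log_ratio_s)).sum()
    )
    g_b = float(-(status.sum() * shape) + (w * shape * (ue - us)).sum())
    g_beta = X.T @ (status - w * (ue - us))
    return f, -np.concatenate([[g_a, g_b], g_beta])


def _numeric_hessian(fun, x, rel_step=1e-5):
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_weibull_ph(td: TransitionDataset, max_restarts: int = 3) -> WeibullFit:
    """Maximum likelihood for a left-truncated Weibull PH intensity.

    Parameterised as (log shape, log scale, beta); standard errors from
    the observed information (numeric Hessian at the optimum).  Fits with
    fewer than two events, failed optimisation after jittered restarts,
    or a non-positive-definite information matrix are flagged
    ``converged=False`` rather than raising.
    """
    entry, exit_, status, X = td.arrays()
    p = X.shape[1]
    n_events = int(status.sum())
    dummy_vcov = np.full((2 + p, 2 + p), np.nan)
    if n_events < 2:
        return WeibullFit(np.nan, np.nan, np.full(p, np.nan), dummy_vcov,
                          td.covariates, False, np.nan, n_events)

    x0 = np.concatenate([[0.0, np.log(max(np.mean(exit_ - entry), 1e-3))], np.zeros(p)])
    args = (entry, exit_, status, X)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.5, size=x0.size)
        res = optimize.minimize(_weibull_negloglik_grad, start, args=args, jac=True,
                                method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
        # line searches can stall with a tiny residual gradient; that is
        # still an acceptable optimum
        ok_grad = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-4 * max(1.0, abs(res.fun))
        if not (res.success or ok_grad):
            # derivative-free fallback from the same start, then re-polish
            nm = optimize.minimize(_weibull_negloglik, start, args=args, method="Nelder-Mead",
                                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
            res = optimize.minimize(_weibull_negloglik_grad, nm.x, args=args, jac=True,
                                    method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
            ok_grad = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-4 * max(1.0, abs(res.fun))
        if best is None or res.fun < best.fun:
            best = res
        if (res.success or ok_grad) and np.isfinite(res.fun):
            best = res
            break
    ok = best is not None and np.isfinite(best.fun)
    shape = float(np.exp(best.x[0])) if ok else np.nan
    scale = float(np.exp(best.x[1])) if ok else np.nan
    beta = best.x[2:] if ok else np.full(p, np.nan)
    vcov = dummy_vcov
    converged = False
    if ok:
        H = _numeric_hessian(lambda x: _weibull_negloglik(x, *args), best.x)
        try:
            vcov = np.linalg.inv(H)
            converged = bool(np.all(np.linalg.eigvalsh(H) > 0))
        except np.linalg.LinAlgError:
            converged = False
    if not converged:
        logger.info("transition %s: Weibull fit flagged non-converged", td.transition)
    return WeibullFit(
        shape=shape,
        scale=scale,
        beta=np.asarray(beta, dtype=float),
        vcov=vcov,
        covariates=td.covariates,
        converged=converged,
        loglik=float(-best.fun) if ok else np.nan,
        n_events=n_events,
    )


# --------------------------------------------------------------------------
# Markov test


def markov_test(
    cohort: pd.DataFrame, model: str = "cox", on_violation: str = "error"
) -> MarkovTestFit:
    """Test the Markov assumption on the 1->2 transition.

    The time from transplant to aGvHD, d, is added as a covariate to the
    aGvHD -> relapse/death intensity model.  Under the Markov DGM the
    true coefficient gamma_12 is zero.  Returns the estimate, its SE and
    a Wald 95% CI.
    """
    tds = to_transition_datasets(cohort, on_violation=on_violation)
    td12 = tds["12"]
    frame = td12.frame.copy()
    frame["d"] = frame["entry"]
    td = TransitionDataset(frame, "12", ("z1", "z2", "d"))
    if frame["status"].sum() < 2:
        raise ValueError("need at least 2 events in transition 1->2")
    if model == "cox":
        fit = fit_cox(td)
        idx = td.covariates.index("d")
        gamma = float(fit.beta[idx])
        se = float(np.sqrt(fit.vcov[idx, idx]))
    elif model == "weibull":
        fit = fit_weibull_ph(td)
        if not fit.converged:
            raise RuntimeError("Weibull Markov-test fit did not converge")
        idx = 2 + td.covariates.index("d")
        gamma = float(fit.beta[td.covariates.index("d")])
        se = float(np.sqrt(fit.vcov[idx, idx]))
    else:
        raise ValueError("model must be 'cox' or 'weibull'")
    half = 1.959963984540054 * se
    return MarkovTestFit(gamma=gamma, se=se, ci=(gamma - half, gamma + half), fit=fit)
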