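"""Orchestration of the factorial simulation study.

A study cell is one (missingness scenario, missing-data method, analysis
model) combination.  Each replicate simulates a cohort, imposes the
scenario's missingness, imputes (or complete-case filters), fits the
three transition models plus the Markov-assumption test to every
completed dataset, pools across imputations by Rubin's rules, and
records point estimates with model-based intervals.  Replicate seeds are
a pure function of (master seed, replicate index), so any replicate is
reproducible in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimands import aalen_johansen, relos, state_probs_weibull
from .imputation import MIConfig, cca_filter, fcs_impute
from .missingness import apply_scenario
from .msm_fit import fit_cox, fit_weibull_ph, markov_test, to_transition_datasets
from .pooling_performance import evaluate, rubins_rules
from .simulator import DGMConfig, simulate_cohort, true_state_probs

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_replicate", "run_cell", "summarize_cell", "true_values", "report"]

Z975 = 1.959963984540054

# estimand -> (transition, covariate index) for the regression parameters
BETA_ESTIMANDS = {
    "beta011": ("01", 0),
    "beta021": ("02", 0),
    "beta121": ("12", 0),
    "beta122": ("12", 1),
}


@dataclass(frozen=True)
class StudyConfig:
    """Full factorial study configuration.

    ``n_replicates`` defaults to a desk-scale 200; the headline study
    design uses 1000.  ``estimands`` controls what each replicate
    records: regression parameters and the Markov test are always cheap;
    RELOS (with its bootstrap SE under Cox models) is opt-in because it
    dominates the run time.
    """

    dgm: DGMConfig = field(default_factory=DGMConfig)
    scenarios: tuple[int, ...] = (0,)
    methods: tuple[str, ...] = ("PMM",)
    models: tuple[str, ...] = ("cox",)
    n_replicates: int = 200
    m_imputations: int = 5
    n_iterations: int = 5
    donor_pool_size: int = 5
    bootstrap_b: int = 50
    horizon: float = 730.0
    z_pattern: tuple[float, float] = (0.0, 0.0)
    master_seed: int = 0
    include_relos: bool = False


def _replicate_seeds(master_seed: int, replicate: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))
    sim, mask, imp = (int(c.generate_state(1)[0]) for c in ss.spawn(3))
    return sim, mask, imp


def _fit_one(completed: pd.DataFrame, model: str, on_violation: str) -> dict[str, tuple[float, float]]:
    """Point estimate and variance of every estimand on one completed dataset."""
    tds = to_transition_datasets(completed, on_violation=on_violation)
    out: dict[str, tuple[float, float]] = {}
    if model == "cox":
        fits = {k: fit_cox(td) for k, td in tds.items()}
        for name, (tr, j) in BETA_ESTIMANDS.items():
            f = fits[tr]
            out[name] = (float(f.beta[j]), float(f.vcov[j, j]))
    elif model == "weibull":
        fits = {k: fit_weibull_ph(td) for k, td in tds.items()}
        for name, (tr, j) in BETA_ESTIMANDS.items():
            f = fits[tr]
            if not f.converged:
                raise RuntimeError(f"Weibull fit {tr} did not converge")
            out[name] = (float(f.beta[j]), float(f.vcov[2 + j, 2 + j]))
    else:
        raise ValueError("model must be 'cox' or 'weibull'")
    mk = markov_test(completed, model=model, on_violation=on_violation)
    out["gamma12"] = (mk.gamma, mk.se**2)
    return out


def run_replicate(
    config: StudyConfig, scenario: int, method: str, models: tuple[str, ...], replicate: int
) -> dict:
    """One simulation replicate of one study cell; returns a flat record."""
    sim_seed, mask_seed, imp_seed = _replicate_seeds(config.master_seed, replicate)
    dgm = DGMConfig(
        spec01=config.dgm.spec01,
        spec02=config.dgm.spec02,
        spec12=config.dgm.spec12,
        p_z1=config.dgm.p_z1,
        p_z2=config.dgm.p_z2,
        censor_min=config.dgm.censor_min,
        censor_max=config.dgm.censor_max,
        n_patients=config.dgm.n_patients,
        seed=sim_seed,
    )
    cohort = simulate_cohort(dgm)
    row: dict = {"replicate": replicate, "valid": True}

    if method == "FULL":
        completed_sets, on_violation, df_n = [cohort], "error", len(cohort)
    else:
        masked = apply_scenario(cohort, scenario, seed=mask_seed)
        if method == "CCA":
            subset, n_dropped = cca_filter(masked)
            row["n_dropped"] = n_dropped
            completed_sets, on_violation, df_n = [subset], "error", len(subset)
        else:
            mi = fcs_impute(
                masked,
                MIConfig(
                    method=method,
                    m_imputations=config.m_imputations,
                    n_iterations=config.n_iterations,
                    donor_pool_size=config.donor_pool_size,
                    seed=imp_seed,
                ),
            )
            row["ordering_violations"] = mi.ordering_violations
            completed_sets, on_violation, df_n = mi.datasets, "drop", len(cohort)

    for model in models:
        per_imp: list[dict] = []
        n_failed = 0
        for completed in completed_sets:
            try:
                per_imp.append(_fit_one(completed, model, on_violation))
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                n_failed += 1
                logger.debug("replicate %d, model %s: fit excluded (%s)", replicate, model, exc)
        row[f"{model}_n_excluded"] = n_failed
        if not per_imp or n_failed > len(completed_sets) / 2:
            row["valid"] = False
            continue
        estimand_names = per_imp[0].keys()
        for name in estimand_names:
            ests = [r[name][0] for r in per_imp]
            vars_ = [r[name][1] for r in per_imp]
            if len(ests) >= 2:
                pooled = rubins_rules(ests, vars_, df_complete=df_n - 5)
                est, se, lo, hi = pooled.estimate, pooled.se, *pooled.ci
            else:
                est, se = ests[0], float(np.sqrt(vars_[0]))
                lo, hi = est - Z975 * se, est + Z975 * se
            row[f"{model}_{name}_est"] = est
            row[f"{model}_{name}_se"] = se
            row[f"{model}_{name}_lo"] = lo
            row[f"{model}_{name}_hi"] = hi
        if config.include_relos:
            _add_relos(row, model, completed_sets, config, on_violation)
    return row


def _add_relos(row, model, completed_sets, config, on_violation):
    from .estimands import bootstrap_se_relos, delta_se_relos

    ests: dict[str, list[float]] = {f"e{b}": [] for b in range(3)}
    vars_: dict[str, list[float]] = {f"e{b}": [] for b in range(3)}
    for i, completed in enumerate(completed_sets):
        tds = to_transition_datasets(completed, on_violation=on_violation)
        if model == "cox":
            fits = {k: fit_cox(td) for k, td in tds.items()}
            path = aalen_johansen(fits, config.z_pattern, config.horizon)
            ses = bootstrap_se_relos(
                completed, config.z_pattern, config.horizon, config.bootstrap_b,
                seed=i, on_violation=on_violation,
            )
        else:
            fits = {k: fit_weibull_ph(td) for k, td in tds.items()}
            path = state_probs_weibull(fits, config.z_pattern, config.horizon)
            ses = delta_se_relos(fits, config.z_pattern, config.horizon)
        vals = relos(path, config.horizon)
        for b in range(3):
            ests[f"e{b}"].append(vals[f"e{b}"])
            vars_[f"e{b}"].append(ses[f"e{b}"] ** 2)
    for key in ests:
        if len(ests[key]) >= 2:
            pooled = rubins_rules(ests[key], vars_[key])
            est, se, lo, hi = pooled.estimate, pooled.se, *pooled.ci
        else:
            est, se = ests[key][0], float(np.sqrt(vars_[key][0]))
            lo, hi = est - Z975 * se, est + Z975 * se
        # intervals clipped to the plausible range [0, horizon]
        lo, hi = max(lo, 0.0), min(hi, config.horizon)
        row[f"{model}_{key}_est"] = est
        row[f"{model}_{key}_se"] = se
        row[f"{model}_{key}_lo"] = lo
        row[f"{model}_{key}_hi"] = hi


def run_cell(
    config: StudyConfig, scenario: int, method: str, model=None
) -> pd.DataFrame:
    """Run all replicates of one study cell.

    ``model`` may be a single model name or a sequence; passing both
    "cox" and "weibull" fits both to the same imputed datasets.
    Replicate-level failures are logged and recorded, never fatal, but a
    cell with more than 5% failed replicates is flagged in ``attrs``.
    """
    models = (model,) if isinstance(model, str) else tuple(model or config.models)
    rows = []
    n_failed = 0
    for r in range(config.n_replicates):
        try:
            rows.append(run_replicate(config, scenario, method, models, r))
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            n_failed += 1
            logger.warning("replicate %d failed outright: %s", r, exc)
    out = pd.DataFrame(rows)
    out.attrs["scenario"] = scenario
    out.attrs["method"] = method
    out.attrs["models"] = models
    out.attrs["n_failed"] = n_failed
    out.attrs["flagged"] = n_failed > 0.05 * config.n_replicates
    if out.attrs["flagged"]:
        logger.warning("cell (%s, %s): %d replicates failed", scenario, method, n_failed)
    return out


def true_values(config: StudyConfig) -> dict[str, float]:
    """True estimand values under the configured DGM."""
    truths = {
        "beta011": config.dgm.spec01.coefficients[0],
        "beta021": config.dgm.spec02.coefficients[0],
        "beta121": config.dgm.spec12.coefficients[0],
        "beta122": config.dgm.spec12.coefficients[1],
        "gamma12": 0.0,
    }
    if config.include_relos:
        grid = np.arange(0.0, config.horizon + 0.05, 0.1)
        path = true_state_probs(config.dgm, config.z_pattern, grid)
        truths.update(relos(path, config.horizon))
    return truths


def summarize_cell(cell: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Performance measures per (model, estimand) for one cell's replicates."""
    truths = true_values(config)
    valid = cell[cell["valid"]] if "valid" in cell else cell
    rows = []
    for model in cell.attrs.get("models", ("cox",)):
        for name, truth in truths.items():
            cols = {s: f"{model}_{name}_{s}" for s in ("est", "se", "lo", "hi")}
            if cols["est"] not in valid.columns:
                continue
            sub = valid[list(cols.values())].dropna()
            sub = sub.rename(columns={v: k for k, v in cols.items()})
            perf = evaluate(sub, truth)
            rows.append(
                {
                    "scenario": cell.attrs.get("scenario"),
                    "method": cell.attrs.get("method"),
                    "model": model,
                    "estimand": name,
                    "truth": truth,
                    **perf,
                }
            )
    return pd.DataFrame(rows)


def report(summaries: pd.DataFrame, out_dir) -> dict[str, str]:
    """Write the summary CSV and a standardized-bias lollipop figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if len(summaries) == 0:
        raise ValueError("no cell summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "performance_summary.csv"
    summaries.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.35 * len(summaries)))
    labels = [
        f"s{r.scenario}/{r.method}/{r.model}/{r.estimand}" for r in summaries.itertuples()
    ]
    y = np.arange(len(summaries))
    ax.hlines(y, 0, summaries["std_bias"], color="0.6")
    ax.plot(summaries["std_bias"], y, "o", color="black")
    ax.axvline(0, color="0.3", lw=0.8)
    for ref in (-0.5, 0.5):
        ax.axvline(ref, color="0.8", ls="--", lw=0.8)
    ax.set_yticks(y, labels, fontsize=7)
    ax.set_xlabel("standardized bias")
    fig.tight_layout()
    fig_path = out_dir / "standardized_bias.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return {"summary_csv": str(csv_path), "figure": str(fig_path)}
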