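"""Missing-data mechanisms for event times.

Masking never alters event indicators or covariates; only time values
become missing (NaN, with the corresponding flag set).

* MCAR — a random 30% of all recorded time values across both columns
  and all patients, regardless of event type, so that completeness is
  independent of the pathway (the condition under which complete-case
  analysis is unbiased).
* Scenarios 1-11 — combinations of MAR rules (masking probability a
  printed function of the double-cord covariate z2) and MNAR rules
  (deterministic masking of times below the 30th or above the 70th
  empirical percentile of the relevant event-time distribution).  These
  mechanisms act on experienced event times only: the aGvHD time of a
  patient with ``aghd_status == 1`` and the relapse/death time of one
  with ``rd_status == 1``; censoring values are untouched.  The three
  rule slots are: time to aGvHD, time to relapse/death without prior
  aGvHD, and time to relapse/death after aGvHD.  Threshold percentiles
  are recomputed within each dataset from the experienced event times;
  the relapse/death percentile pools both pathways.

For a patient who experienced relapse/death without aGvHD the
``aghd_time`` column carries the relapse/death time by convention, so a
scenario masking that event time blanks both columns (one underlying
missing value).  MCAR masks the two columns independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MissingnessScenario", "apply_mcar", "apply_scenario", "missingness_report"]


def _mar_aghd(z2: np.ndarray) -> np.ndarray:
    return 0.2 * (1.0 + z2)


def _mar_rd(z2: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - 0.8 * z2)


@dataclass(frozen=True)
class MissingnessScenario:
    """One row of the scenario table.

    Each rule is ``None`` (never missing), ``("prob", f)`` with f a
    function of z2 giving the masking probability, or
    ``("threshold", q, side)`` masking deterministically the times
    strictly below (side="lower") the q-th percentile or strictly above
    (side="upper") it.
    """

    scenario_id: int
    aghd_rule: tuple | None
    rd_without_rule: tuple | None
    rd_after_rule: tuple | None
    description: str = ""


_LOWER30 = ("threshold", 30.0, "lower")
_UPPER70 = ("threshold", 70.0, "upper")
_PROB_AGHD = ("prob", _mar_aghd)
_PROB_RD = ("prob", _mar_rd)

SCENARIOS: dict[int, MissingnessScenario] = {
    1: MissingnessScenario(1, _PROB_AGHD, None, None, "aGvHD MAR"),
    2: MissingnessScenario(2, _LOWER30, None, None, "aGvHD MNAR (smallest)"),
    3: MissingnessScenario(3, None, _PROB_RD, None, "relapse/death MAR (conditional on aGvHD)"),
    4: MissingnessScenario(4, None, _PROB_RD, _PROB_RD, "relapse/death MAR"),
    5: MissingnessScenario(5, None, _LOWER30, _LOWER30, "relapse/death MNAR (smallest)"),
    6: MissingnessScenario(6, _PROB_AGHD, _PROB_RD, _PROB_RD, "aGvHD MAR & relapse/death MAR"),
    7: MissingnessScenario(7, _LOWER30, _PROB_RD, _PROB_RD, "aGvHD MNAR (smallest) & RD MAR"),
    8: MissingnessScenario(8, _UPPER70, _PROB_RD, _PROB_RD, "aGvHD MNAR (largest) & RD MAR"),
    9: MissingnessScenario(9, _PROB_AGHD, _LOWER30, _LOWER30, "aGvHD MAR & RD MNAR (smallest)"),
    10: MissingnessScenario(10, _PROB_AGHD, _UPPER70, _UPPER70, "aGvHD MAR & RD MNAR (largest)"),
    11: MissingnessScenario(11, _LOWER30, _LOWER30, _LOWER30, "aGvHD MNAR & RD MNAR (smallest)"),
}


def _apply_mask(
    cohort: pd.DataFrame,
    mask_aghd: np.ndarray,
    mask_rd: np.ndarray,
    mirror_blank: bool = True,
) -> pd.DataFrame:
    out = cohort.copy()
    out["aghd_time"] = out["aghd_time"].astype(float)
    out["rd_time"] = out["rd_time"].astype(float)
    out.loc[mask_aghd, "aghd_time"] = np.nan
    out.loc[mask_aghd, "aghd_time_missing"] = True
    out.loc[mask_rd, "rd_time"] = np.nan
    out.loc[mask_rd, "rd_time_missing"] = True
    if mirror_blank:
        # without aGvHD the aghd_time column mirrors the relapse/death
        # time (one underlying value), so masking it blanks both columns
        mirror = mask_rd & (cohort["aghd_status"].to_numpy() == 0)
        out.loc[mirror, "aghd_time"] = np.nan
    return out


def apply_mcar(cohort: pd.DataFrame, proportion: float = 0.30, seed: int = 0) -> pd.DataFrame:
    """Mask a fixed random fraction of all recorded time values.

    Exactly ``round(proportion * 2n)`` of the 2n time values (the aGvHD
    and relapse/death columns of every patient, censoring values
    included) are drawn uniformly without replacement, regardless of the
    event type.  Completeness is therefore independent of a patient's
    pathway — the property that makes complete-case analysis unbiased
    under this mechanism and under no other.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    n_mask = int(round(proportion * 2 * n))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(2 * n, size=n_mask, replace=False)
    mask_aghd = np.zeros(n, dtype=bool)
    mask_rd = np.zeros(n, dtype=bool)
    mask_aghd[chosen[chosen < n]] = True
    mask_rd[chosen[chosen >= n] - n] = True
    return _apply_mask(cohort, mask_aghd, mask_rd, mirror_blank=False)


def apply_scenario(cohort: pd.DataFrame, scenario, seed: int = 0) -> pd.DataFrame:
    """Apply one of scenarios 1-11 (or 0 for MCAR at 30%).

    Probabilistic rules mask each eligible time independently with the
    printed probability evaluated at the patient's z2.  Threshold rules
    compute the stated percentile of the within-dataset experienced
    event-time distribution (aGvHD times for the aGvHD rule; relapse/death
    times pooled over both pathways for the relapse/death rules) and mask
    with strict inequality; exact ties with the threshold are masked.
    """
    if isinstance(scenario, int):
        if scenario == 0:
            return apply_mcar(cohort, 0.30, seed)
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario id {scenario}")
        scenario = SCENARIOS[scenario]

    rng = np.random.default_rng(seed)
    aghd_status = cohort["aghd_status"].to_numpy()
    rd_status = cohort["rd_status"].to_numpy()
    z2 = cohort["z2"].to_numpy(dtype=float)
    aghd_time = cohort["aghd_time"].to_numpy(dtype=float)
    rd_time = cohort["rd_time"].to_numpy(dtype=float)

    elig_aghd = aghd_status == 1
    elig_rd_without = (rd_status == 1) & (aghd_status == 0)
    elig_rd_after = (rd_status == 1) & (aghd_status == 1)

    def percentile(values: np.ndarray, q: float) -> float:
        if values.size < 2:
            raise ValueError("need at least 2 experienced events to form a percentile")
        return float(np.percentile(values, q))

    def evaluate(rule, eligible: np.ndarray, times: np.ndarray, pool: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(cohort), dtype=bool)
        if rule is None:
            return mask
        kind = rule[0]
        if kind == "prob":
            p = rule[1](z2)
            mask[eligible] = rng.random(eligible.sum()) < p[eligible]
        elif kind == "threshold":
            _, q, side = rule
            thr = percentile(pool, q)
            # strict inequality with exact ties also masked, i.e. <= / >=
            if side == "lower":
                mask[eligible] = times[eligible] <= thr
            else:
                mask[eligible] = times[eligible] >= thr
        else:
            raise ValueError(f"unknown rule kind {kind!r}")
        return mask

    aghd_pool = aghd_time[elig_aghd]
    rd_pool = rd_time[rd_status == 1]

    mask_aghd = evaluate(scenario.aghd_rule, elig_aghd, aghd_time, aghd_pool)
    mask_rd = evaluate(scenario.rd_without_rule, elig_rd_without, rd_time, rd_pool)
    mask_rd |= evaluate(scenario.rd_after_rule, elig_rd_after, rd_time, rd_pool)
    return _apply_mask(cohort, mask_aghd, mask_rd)


def missingness_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts of patients by missingness pattern and event combination."""
    events = np.where(
        cohort["aghd_status"] == 1,
        np.where(cohort["rd_status"] == 1, "aGvHD+RD", "aGvHD only"),
        np.where(cohort["rd_status"] == 1, "RD only", "censored"),
    )
    pattern = np.where(
        cohort["aghd_time_missing"],
        np.where(cohort["rd_time_missing"], "both missing", "aGvHD time missing"),
        np.where(cohort["rd_time_missing"], "RD time missing", "complete"),
    )
    tab = (
        pd.DataFrame({"events": events, "pattern": pattern})
        .groupby(["events", "pattern"])
        .size()
        .rename("n_patients")
        .reset_index()
    )
    tab["percent"] = 100.0 * tab["n_patients"] / len(cohort)
    return tab


def targeted_masked_fraction(cohort: pd.DataFrame, scenario) -> float:
    """Masked fraction among event times the scenario's rules target.

    Each mechanism sets roughly 30% of the event times it acts on to
    missing; mechanisms that leave an event type untouched exclude it
    from this denominator.
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    aghd_status = cohort["aghd_status"].to_numpy()
    rd_status = cohort["rd_status"].to_numpy()
    target = np.zeros(len(cohort), dtype=int)
    masked = np.zeros(len(cohort), dtype=int)
    if scenario.aghd_rule is not None:
        elig = aghd_status == 1
        target += elig
        masked += elig & cohort["aghd_time_missing"].to_numpy()
    if scenario.rd_without_rule is not None:
        elig = (rd_status == 1) & (aghd_status == 0)
        target += elig
        masked += elig & cohort["rd_time_missing"].to_numpy()
    if scenario.rd_after_rule is not None:
        elig = (rd_status == 1) & (aghd_status == 1)
        target += elig
        masked += elig & cohort["rd_time_missing"].to_numpy()
    return masked.sum() / target.sum() if target.sum() else float("nan")


def masked_fraction(cohort: pd.DataFrame) -> float:
    """Fraction of experienced event times that are masked."""
    n_aghd = int((cohort["aghd_status"] == 1).sum())
    n_rd = int((cohort["rd_status"] == 1).sum())
    n_masked = int(
        ((cohort["aghd_status"] == 1) & cohort["aghd_time_missing"]).sum()
        + ((cohort["rd_status"] == 1) & cohort["rd_time_missing"]).sum()
    )
    total = n_aghd + n_rd
    return n_masked / total if total else float("nan")
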