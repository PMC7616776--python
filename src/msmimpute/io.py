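"""CSV / YAML round-tripping for cohorts and configurations."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .simulator import COHORT_COLUMNS, DGMConfig, WeibullPHSpec

__all__ = ["write_cohort", "read_cohort", "dgm_config_to_dict", "dgm_config_from_dict",
           "load_dgm_config", "save_dgm_config"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing times become empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks required columns: {missing_cols}")
    for c in ("aghd_time_missing", "rd_time_missing"):
        df[c] = df[c].astype(bool)
    for c in ("id", "z1", "z2", "aghd_status", "rd_status"):
        df[c] = df[c].astype(int)
    return df


def dgm_config_to_dict(config: DGMConfig) -> dict:
    d = asdict(config)
    for k in ("spec01", "spec02", "spec12"):
        d[k]["coefficients"] = list(d[k]["coefficients"])
    return d


def dgm_config_from_dict(d: dict) -> DGMConfig:
    kwargs = dict(d)
    for k in ("spec01", "spec02", "spec12"):
        if k in kwargs and isinstance(kwargs[k], dict):
            kwargs[k] = WeibullPHSpec(**kwargs[k])
    return DGMConfig(**kwargs)


def load_dgm_config(path) -> DGMConfig:
    with open(path) as fh:
        return dgm_config_from_dict(yaml.safe_load(fh) or {})


def save_dgm_config(config: DGMConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dgm_config_to_dict(config), sort_keys=False))
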