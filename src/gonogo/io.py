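"""Trial-table CSV dialect, run configuration and validation.

Trial tables are plain CSV, one row per trial, with the columns in
:data:`gonogo.task.TRIAL_COLUMNS`.  Reading validates every categorical
field against its enumeration and re-checks the Go-cost arithmetic
(delivered == base - 1 after Go); violations raise a parse error naming
the offending row.

Run configurations are YAML with sections ``cohort``, ``task``, ``mcmc``,
``metrics`` and ``seeds``.  Seeds are never defaulted: a stage whose seed
is absent from both the config and the command line is an error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import CARD_INDEX, GO_COST, TRIAL_COLUMNS, Card

__all__ = ["read_trial_table", "write_trial_table", "validate_trial_table",
           "load_run_config", "cohort_config_from_run_config", "mcmc_config_from_run_config"]

_VALID = {"control": {"high", "low"}, "tdcs": {"stim", "sham"},
          "card": set(CARD_INDEX), "response": {"go", "nogo"},
          "block": {1, 2}, "correct": {0, 1}, "base_points": {-10, 0, 10}}


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check dialect conformance; raises ValueError naming the first bad row."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    for col in ("block", "trial", "base_points", "delivered_points", "correct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise ValueError(f"row {int(np.nonzero(bad.to_numpy())[0][0])}: "
                             f"non-integer value in column {col!r}")
        df[col] = vals.astype(int)
    for col in ("control", "tdcs", "card", "response", "block", "correct",
                "base_points"):
        ok = df[col].isin(_VALID[col])
        if not ok.all():
            i = int(np.nonzero(~ok.to_numpy())[0][0])
            raise ValueError(f"row {i}: invalid {col} label {df[col].iloc[i]!r}")
    cost = np.where(df["response"] == "go", GO_COST, 0)
    bad = df["delivered_points"].to_numpy() != df["base_points"].to_numpy() - cost
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(f"row {i}: delivered_points inconsistent with Go-cost "
                         f"(base {df['base_points'].iloc[i]}, "
                         f"response {df['response'].iloc[i]!r}, "
                         f"delivered {df['delivered_points'].iloc[i]})")
    required = df["card"].map(lambda c: Card(c).required_action)
    bad = df["correct"].to_numpy() != (df["response"].to_numpy() == required.to_numpy())
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(f"row {i}: 'correct' flag inconsistent with card/response")
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV; an empty file with a header is fine."""
    df = pd.read_csv(path)
    if len(df) == 0:
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table is missing columns: {missing}")
        return df
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def load_run_config(path) -> dict:
    """Load a YAML run configuration; returns a plain nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg


def require_seed(cfg: dict, stage: str, override: int | None = None) -> int:
    """Resolve a stage seed: CLI override first, then the config's seeds section."""
    if override is not None:
        return int(override)
    seed = (cfg.get("seeds") or {}).get(stage)
    if seed is None:
        raise ValueError(f"missing seed for stage {stage!r}: pass --seed or add "
                         f"seeds.{stage} to the config")
    return int(seed)


def cohort_config_from_run_config(cfg: dict, seed: int):
    """Build a CohortConfig from the ``cohort`` and ``task`` config sections."""
    from .cohort import CohortConfig, default_coefficients, study_like_coefficients

    cohort = cfg.get("cohort") or {}
    task = cfg.get("task") or {}
    kwargs = {"seed": seed}
    if "n_per_group" in cohort:
        kwargs["n_per_group"] = {(k.split("_")[0], k.split("_")[1]): int(v)
                                 for k, v in cohort["n_per_group"].items()}
    preset = cohort.get("preset")
    if preset == "study_like":
        kwargs["coefficients"] = study_like_coefficients()
    elif preset not in (None, "default"):
        raise ValueError(f"unknown cohort preset {preset!r}")
    if "coefficients" in cohort:
        base = kwargs.get("coefficients", default_coefficients())
        for param, coefs in cohort["coefficients"].items():
            base[param] = {str(k): float(v) for k, v in coefs.items()}
        kwargs["coefficients"] = base
    if "subject_sd" in cohort:
        kwargs["subject_sd"] = {k: float(v) for k, v in cohort["subject_sd"].items()}
    for key in ("n_reps", "contingency", "contingency_mode", "reward_scale"):
        if key in task:
            kwargs[key] = task[key]
    return CohortConfig(**kwargs)


def mcmc_config_from_run_config(cfg: dict, seed: int):
    from .inference import DESK_MCMC, McmcConfig

    mcmc = cfg.get("mcmc") or {}
    return McmcConfig(seed=seed,
                      n_chains=int(mcmc.get("n_chains", DESK_MCMC.n_chains)),
                      warmup=int(mcmc.get("warmup", DESK_MCMC.warmup)),
                      draws=int(mcmc.get("draws", DESK_MCMC.draws)),
                      rhat_threshold=float(mcmc.get("rhat_threshold",
                                                    DESK_MCMC.rhat_threshold)))
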