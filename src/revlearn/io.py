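"""Reading and writing of event tables, configs, and fit outputs.

Event tables are tab-separated text with one row per trial and the header
``subject_id, session, trial, block_id, block_type, choice, outcome, valid,
correct, reversal_cause``. Configs are flat key-value YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import GroupPrior
from .models import ModelSpec
from .task import EVENT_COLUMNS, TaskConfig

_SEP = "\t"


def write_events(events: pd.DataFrame, path) -> None:
    df = events.copy()
    df["valid"] = df["valid"].astype(int)
    df["correct"] = df["correct"].astype(int)
    df.to_csv(path, sep=_SEP, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_SEP, dtype={"subject_id": str},
                     keep_default_na=False, na_values=[])
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    df["valid"] = df["valid"].astype(int).astype(bool)
    df["correct"] = df["correct"].astype(int).astype(bool)
    for col in ("choice", "outcome", "reversal_cause"):
        df[col] = df[col].replace("", None)
    return df


def write_task_config(config: TaskConfig, path) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_task_config(path) -> TaskConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("block_type_cycle", "iti_jitter_s"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return TaskConfig(**data)


def write_group_prior(prior: GroupPrior, spec: ModelSpec, path) -> None:
    data = {
        "model": spec.name,
        "parameters": list(spec.parameter_names),
        "mu": [float(x) for x in prior.mu],
        "sigma2": [float(x) for x in prior.sigma2],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_group_prior(path) -> tuple[str, GroupPrior]:
    data = yaml.safe_load(Path(path).read_text())
    return data["model"], GroupPrior(np.array(data["mu"]), np.array(data["sigma2"]))
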