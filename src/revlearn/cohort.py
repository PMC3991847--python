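"""Seeded synthetic cohorts and behavioral summaries.

Three default phenotypes are provided, generated from the latent-state model
with separate reward/punishment sensitivities:

- ``HC-like`` (n=24): high stay probability and high sensitivities; adapts
  quickly after reversals.
- ``SZ-goodfit-like`` (n=13): lowered stay probability (elevated switch
  tendency) with intact sensitivities.
- ``SZ-poorfit-like`` (n=11): near-zero reward sensitivity; performs at
  chance and is typically not fitted better than chance.

The generating parameter values are synthetic defaults chosen to reproduce
the qualitative phenotype contrasts; they are not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import task as _task
from .fitting import transform, untransform
from .models import get_model, simulate_agent

#: block cycle emulating the full design, including 50/50 neutral blocks
STUDY_CYCLE = ("right_better", "left_better", "neutral")


@dataclass
class SubgroupSpec:
    name: str
    n: int
    model: str  # registry name, e.g. "HMM-RP"
    params_mean: dict  # natural scale
    params_sd: float | dict = 0.3  # sd on the transformed scale

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("subgroup size must be >= 1")


@dataclass
class CohortSpec:
    subgroups: list
    task: _task.TaskConfig = field(default_factory=_task.TaskConfig)
    seed: int = 0


def default_cohort_spec(seed: int = 0, sd: float = 0.3) -> CohortSpec:
    task = _task.TaskConfig(block_type_cycle=STUDY_CYCLE)
    return CohortSpec(
        subgroups=[
            SubgroupSpec("HC-like", 24, "HMM-RP",
                         {"gamma": 0.92, "c_rew": 2.5, "c_pun": 2.5}, sd),
            SubgroupSpec("SZ-goodfit-like", 13, "HMM-RP",
                         {"gamma": 0.80, "c_rew": 2.5, "c_pun": 2.5}, sd),
            SubgroupSpec("SZ-poorfit-like", 11, "HMM-RP",
                         {"gamma": 0.80, "c_rew": 0.03, "c_pun": 0.05}, sd),
        ],
        task=task,
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject of the cohort.

    Per-subject parameters are drawn around the subgroup mean on the
    transformed scale. Returns ``(events, truth)``: the concatenated event
    table and a long-format ground-truth parameter table
    (subject_id, subgroup, model, parameter, value).
    """
    rng = np.random.default_rng(spec.seed)
    events = []
    truth_rows = []
    for sub in spec.subgroups:
        mspec = get_model(sub.model)
        mu = transform(sub.params_mean, mspec)
        if isinstance(sub.params_sd, dict):
            sd = np.array([sub.params_sd[p] for p in mspec.parameter_names], dtype=float)
        else:
            sd = np.full(mspec.n_params, float(sub.params_sd))
        for i in range(sub.n):
            subject_id = f"{sub.name}_{i:02d}"
            theta = mu + sd * rng.standard_normal(mspec.n_params)
            params = untransform(theta, mspec)
            sim_seed = int(rng.integers(0, 2**31 - 1))
            events.append(simulate_agent(mspec, params, spec.task, sim_seed, subject_id))
            for pname, value in params.items():
                truth_rows.append({"subject_id": subject_id, "subgroup": sub.name,
                                   "model": sub.model, "parameter": pname,
                                   "value": value})
    return pd.concat(events, ignore_index=True), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# behavioral summaries

@dataclass
class BehavioralSummary:
    per_subject: pd.DataFrame   # percent_correct, reversal counts per subject
    curves: pd.DataFrame        # subject x post-reversal position mean correctness
    group_curves: pd.DataFrame | None = None


def percent_correct(trials: pd.DataFrame) -> float:
    """Percent correct over valid trials of non-neutral blocks."""
    mask = trials["valid"].to_numpy(dtype=bool) & (trials["block_type"] != "neutral")
    if not mask.any():
        return float("nan")
    return 100.0 * float(trials.loc[mask, "correct"].mean())


def reversal_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject counts of criterion- vs. max-length-triggered reversals."""
    causes = trials.dropna(subset=["reversal_cause"])
    rows = []
    for sid, df in causes.groupby("subject_id", sort=True):
        c = df["reversal_cause"].value_counts()
        crit = int(c.get(_task.CAUSE_CRITERION, 0))
        maxlen = int(c.get(_task.CAUSE_MAX_LENGTH, 0))
        rows.append({"subject_id": sid,
                     "criterion_reversals": crit,
                     "max_length_reversals": maxlen,
                     "completed_blocks": crit + maxlen,
                     "total_blocks": len(df)})
    return pd.DataFrame(rows)


def _post_reversal_positions(trials: pd.DataFrame, n_post: int) -> pd.DataFrame:
    """Correctness at positions 1..n_post of every block that follows a reversal."""
    rows = []
    for (sid, session), df in trials.groupby(["subject_id", "session"], sort=True):
        df = df.sort_values("trial")
        block_ids = df["block_id"].unique()
        for bid in block_ids[1:]:  # the session's first block follows no reversal
            blk = df[df["block_id"] == bid].head(n_post)
            for pos, row in enumerate(blk.itertuples(index=False), start=1):
                correct = np.nan
                if row.valid and row.block_type != "neutral":
                    correct = float(row.correct)
                rows.append({"subject_id": sid, "session": session,
                             "position": pos, "correct": correct})
    return pd.DataFrame(rows)


def learning_curves(trials: pd.DataFrame, n_post: int = 10,
                    groups: dict | None = None) -> BehavioralSummary:
    """Post-reversal learning curves plus per-subject summaries.

    Trials are aligned to reversal onsets (block starts after the first block
    of each session); correctness is averaged at positions ``1..n_post``
    within subject, then across subjects (per subgroup when ``groups`` maps
    subject_id to a group). Neutral-block and invalid trials are excluded
    from the averages; blocks shorter than ``n_post`` contribute what they
    have.
    """
    pos = _post_reversal_positions(trials, n_post)
    curves = (pos.groupby(["subject_id", "position"])["correct"]
                 .mean().unstack("position"))

    per_subject = []
    for sid, df in trials.groupby("subject_id", sort=True):
        per_subject.append({"subject_id": sid, "percent_correct": percent_correct(df)})
    per_subject = pd.DataFrame(per_subject)
    rc = reversal_counts(trials)
    if len(rc):
        per_subject = per_subject.merge(rc, on="subject_id", how="left")

    group_curves = None
    if groups is not None:
        gc = curves.copy()
        gc["group"] = [groups.get(s) for s in gc.index]
        group_curves = gc.groupby("group").mean()
    return BehavioralSummary(per_subject, curves, group_curves)
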