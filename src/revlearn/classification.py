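"""Subjective trial labeling from filtered beliefs, and regressor export.

A valid feedback trial is labeled from three binary facts: the outcome, the
consistency of the choice with the belief-preferred side before the outcome,
and whether the preferred latent state changed after the outcome update
("stay"/"switch" is about the next *belief*, not the next action):

======================  ===========  ========================
outcome                 consistency  belief change -> label
======================  ===========  ========================
reward                  consistent   stay   -> informative_reward
reward                  inconsistent switch -> informative_reward
reward                  (otherwise)         -> probabilistic_reward
punishment              consistent   switch -> informative_punishment
punishment              inconsistent stay   -> informative_punishment
punishment              (otherwise)         -> probabilistic_punishment
======================  ===========  ========================

Regressor tables are exported with trial-index onsets; conversion to scanner
time is the consumer's job.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import task as _task
from .models import MODELS, ModelSpec, belief_trajectory, outcome_value

LABELS = (
    "informative_reward", "probabilistic_reward",
    "informative_punishment", "probabilistic_punishment",
)
INVALID_LABEL = "invalid"


def classify_trials(beliefs: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Label each valid feedback trial from its belief trajectory.

    ``beliefs`` must come from :func:`revlearn.models.belief_trajectory` for
    the same trials (fitted HMM-RP in the standard pipeline). Returns a frame
    with ``consistency``, ``belief_change`` and ``label`` columns aligned to
    ``trials``; invalid trials get the nuisance label.

    Tie conventions: a belief of exactly 0.5 before the choice makes any
    choice consistent; a preferred-state change requires a strict crossing of
    0.5, so ties resolve to "stay".
    """
    if len(beliefs) != len(trials):
        raise ValueError("beliefs and trials must align one row per trial")
    b_prior = beliefs["b_prior"].to_numpy(dtype=float)
    b_post = beliefs["b_post"].to_numpy(dtype=float)
    valid = trials["valid"].to_numpy(dtype=bool)
    choice_left = (trials["choice"] == "left").to_numpy()
    rewarded = (trials["outcome"] == _task.REWARD).to_numpy()

    # consistency: chosen side agrees with the belief-preferred side (ties agree)
    consistent = np.where(choice_left, b_prior >= 0.5, b_prior <= 0.5)
    switch = (b_prior - 0.5) * (b_post - 0.5) < 0.0

    informative = np.where(rewarded, consistent != switch, consistent == switch)
    label = np.where(
        rewarded,
        np.where(informative, "informative_reward", "probabilistic_reward"),
        np.where(informative, "informative_punishment", "probabilistic_punishment"),
    )
    out = pd.DataFrame(
        {
            "consistency": pd.array(consistent, dtype="boolean"),
            "belief_change": pd.array(np.where(switch, "switch", "stay"),
                                      dtype="string"),
            "label": label,
        },
        index=trials.index,
    )
    out.loc[~valid, ["consistency", "belief_change"]] = pd.NA
    out.loc[~valid, "label"] = INVALID_LABEL
    return out


def _pe_series(spec: ModelSpec, params: dict, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial prediction errors R - Q_prev(chosen) for the Q-learning families."""
    if spec.family not in ("SA", "DSA"):
        raise ValueError("prediction errors require an SA or DSA model")
    eps = params["epsilon"]
    rho_rew = params["rho_rew"] if spec.rp_variant else params["rho"]
    rho_pun = params["rho_pun"] if spec.rp_variant else params["rho"]
    pe = np.full(len(trials), np.nan)
    q = np.zeros(2)
    session = trials["session"].to_numpy()
    for t, row in enumerate(trials.itertuples(index=False)):
        if t == 0 or session[t] != session[t - 1]:
            q = np.zeros(2)
        if not row.valid:
            continue
        c = 0 if row.choice == "left" else 1
        r = outcome_value(row.outcome, rho_rew, rho_pun)
        pe[t] = r - q[c]
        q[c] += eps * (r - q[c])
        if spec.family == "DSA":
            q[1 - c] += eps * (-r - q[1 - c])
    return pe


def export_regressors(
    trials: pd.DataFrame,
    params: dict,
    kind: str = "pe",
    model: str | ModelSpec | None = None,
) -> pd.DataFrame:
    """Event/regressor table for downstream GLM software.

    ``kind="pe"``: one row per valid feedback trial, name ``feedback_pe``,
    with the trial-wise prediction error of the Q-learning model as
    parametric modulator. ``kind="hmm_events"``: one row per valid trial
    named by its subjective label. Both append invalid trials as a separate
    nuisance class. Onsets are 0-based row indices into ``trials``.
    """
    if isinstance(model, str):
        spec = MODELS[model]
    elif isinstance(model, ModelSpec):
        spec = model
    else:
        spec = MODELS["SA" if kind == "pe" else "HMM-RP"]

    onsets = np.arange(len(trials))
    valid = trials["valid"].to_numpy(dtype=bool)
    if kind == "pe":
        pe = _pe_series(spec, params, trials)
        name = np.where(valid, "feedback_pe", INVALID_LABEL)
        table = pd.DataFrame({"onset_index": onsets, "name": name, "modulator": pe})
    elif kind == "hmm_events":
        beliefs = belief_trajectory(params, trials, spec)
        labels = classify_trials(beliefs, trials)
        table = pd.DataFrame({"onset_index": onsets, "name": labels["label"].to_numpy(),
                              "modulator": np.nan})
    else:
        raise ValueError(f"unknown regressor kind {kind!r}")
    return table


def pre_event_reward_rate(
    trials: pd.DataFrame,
    labels: pd.DataFrame,
    window: int = 10,
) -> pd.DataFrame:
    """Reward rate over the valid trials preceding each labeled event.

    The window never crosses a session boundary; events with fewer than
    ``window`` preceding valid trials use what is available and are flagged
    ``shortened`` (events with no history get a NaN rate). Returns one row
    per labeled valid trial: subject_id, label, rate, n_window, shortened.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    valid = trials["valid"].to_numpy(dtype=bool)
    rewarded = (trials["outcome"] == _task.REWARD).to_numpy(dtype=float)
    session = trials["session"].to_numpy()
    subject = trials["subject_id"].to_numpy()
    label = labels["label"].to_numpy()

    rows = []
    for t in range(len(trials)):
        if not valid[t]:
            continue
        hist = [u for u in range(t - 1, -1, -1)
                if session[u] == session[t] and subject[u] == subject[t] and valid[u]]
        hist = hist[:window]
        rate = float(np.mean(rewarded[hist])) if hist else np.nan
        rows.append({"subject_id": subject[t], "onset_index": t, "label": label[t],
                     "rate": rate, "n_window": len(hist),
                     "shortened": len(hist) < window})
    return pd.DataFrame(rows)


def summarize_pre_event_rates(rates: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Mean pre-event reward rate per (group, label); ``groups`` maps subject to group."""
    df = rates.copy()
    df["group"] = df["subject_id"].map(groups)
    return (df.dropna(subset=["rate"])
              .groupby(["group", "label"], sort=True)["rate"]
              .mean().reset_index())
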