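"""Candidate learning models: SA, DSA and latent-state (HMM) families.

Six models are registered, each family in an equal-sensitivity and a separate
reward/punishment (R/P) variant:

``SA``
    Rescorla-Wagner update of the chosen action's value only,
    ``Q <- Q + eps * (R - Q)`` with outcomes coded ``R = +rho`` (reward) and
    ``R = -rho`` (punishment); choice by a unit-slope logistic of the Q
    difference, so rho doubles as the softmax sensitivity.
``DSA``
    Double update: the chosen action moves toward ``R`` and the unchosen
    action toward ``-R`` with the same learning rate, reflecting the
    anti-symmetric task structure.
``HMM``
    A two-state belief model. State 1 means "left is the good side". The
    belief transitions with stay probability ``gamma``, observations shift
    the belief log-odds by ``+/- c * log(q/(1-q))`` with task contingency
    ``q = 0.8`` and sensitivity ``c`` (split into ``c_rew``/``c_pun`` in the
    R/P variant), and choices probability-match the prior belief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import task as _task
from ._kernels import hmm_loglik, qlearn_loglik

Q_EMIT = 0.8  # task contingency assumed by the belief model


class ParameterError(ValueError):
    """Parameters outside the model's domain."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    family: str  # "SA" | "DSA" | "HMM"
    rp_variant: bool
    parameter_names: tuple
    transforms: tuple  # "logit" -> (0,1), "log" -> (0,inf), "identity" -> R

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


MODELS: dict[str, ModelSpec] = {
    "SA": ModelSpec("SA", "SA", False, ("epsilon", "rho"), ("logit", "log")),
    "SA-RP": ModelSpec("SA-RP", "SA", True,
                       ("epsilon", "rho_rew", "rho_pun"), ("logit", "log", "log")),
    "DSA": ModelSpec("DSA", "DSA", False, ("epsilon", "rho"), ("logit", "log")),
    "DSA-RP": ModelSpec("DSA-RP", "DSA", True,
                        ("epsilon", "rho_rew", "rho_pun"), ("logit", "log", "log")),
    "HMM": ModelSpec("HMM", "HMM", False, ("gamma", "c"), ("logit", "log")),
    "HMM-RP": ModelSpec("HMM-RP", "HMM", True,
                        ("gamma", "c_rew", "c_pun"), ("logit", "log", "log")),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# elementary updates (reference implementations; kernels inline the same math)

def outcome_value(outcome: str, rho_rew: float, rho_pun: float) -> float:
    """Signed outcome R: +rho_rew for reward, -rho_pun for punishment."""
    if outcome == _task.REWARD:
        return rho_rew
    if outcome == _task.PUNISHMENT:
        return -rho_pun
    raise ValueError(f"invalid outcome {outcome!r}")


def sa_update(q: np.ndarray, choice: int, r: float, eps: float) -> np.ndarray:
    """Update only the chosen action's value toward the signed outcome ``r``."""
    if not 0.0 <= eps <= 1.0:
        raise ParameterError("epsilon must lie in [0, 1]")
    q = np.asarray(q, dtype=float).copy()
    q[choice] += eps * (r - q[choice])
    return q


def dsa_update(q: np.ndarray, choice: int, r: float, eps: float) -> np.ndarray:
    """Update the chosen action toward ``r`` and the unchosen toward ``-r``."""
    if not 0.0 <= eps <= 1.0:
        raise ParameterError("epsilon must lie in [0, 1]")
    q = np.asarray(q, dtype=float).copy()
    q[choice] += eps * (r - q[choice])
    q[1 - choice] += eps * (-r - q[1 - choice])
    return q


def q_action_prob(q: np.ndarray) -> np.ndarray:
    """Unit-slope logistic of the Q difference; returns (P(left), P(right))."""
    p_left = expit(q[0] - q[1])
    return np.array([p_left, 1.0 - p_left])


def hmm_transition(b: float, gamma: float) -> float:
    """One step of the two-state stay/switch dynamics on P(state 1)."""
    return gamma * b + (1.0 - gamma) * (1.0 - b)


def hmm_observe(b_prior: float, choice: int, outcome: str, gamma: float,
                c_rew: float, c_pun: float, q_emit: float = Q_EMIT) -> float:
    """Evidence update in log-odds. ``gamma`` is unused but kept for symmetry."""
    d0 = np.log(q_emit / (1.0 - q_emit))
    sign = 1.0 if (choice == 0) == (outcome == _task.REWARD) else -1.0
    w = c_rew if outcome == _task.REWARD else c_pun
    lam = np.log(b_prior / (1.0 - b_prior)) + w * sign * d0
    return float(expit(lam))


def hmm_action_prob(b_prior: float) -> np.ndarray:
    """Probability matching on the prior belief."""
    return np.array([b_prior, 1.0 - b_prior])


# ---------------------------------------------------------------------------
# trial-table encoding and likelihood

def encode_trials(trials: pd.DataFrame):
    """Columns of an event table as kernel-ready arrays.

    Returns ``(choices, outcomes, valid, new_sess)``; invalid trials get
    choice/outcome code -1.
    """
    valid = trials["valid"].to_numpy(dtype=bool)
    choices = np.full(len(trials), -1, dtype=np.int8)
    choices[trials["choice"] == "left"] = 0
    choices[trials["choice"] == "right"] = 1
    outcomes = np.full(len(trials), -1, dtype=np.int8)
    outcomes[trials["outcome"] == _task.REWARD] = 1
    outcomes[trials["outcome"] == _task.PUNISHMENT] = 0
    session = trials["session"].to_numpy()
    subject = trials["subject_id"].to_numpy()
    new_sess = np.zeros(len(trials), dtype=bool)
    if len(trials):
        new_sess[0] = True
        new_sess[1:] = (session[1:] != session[:-1]) | (subject[1:] != subject[:-1])
    if np.any(valid & (choices < 0)):
        raise ValueError("valid trial without a recorded choice")
    if np.any(valid & (outcomes < 0)):
        raise ValueError("valid trial without a recorded outcome")
    return choices, outcomes, valid, new_sess


def _split_sensitivities(spec: ModelSpec, params: dict) -> tuple:
    if spec.family in ("SA", "DSA"):
        eps = params["epsilon"]
        if spec.rp_variant:
            s_rew, s_pun = params["rho_rew"], params["rho_pun"]
        else:
            s_rew = s_pun = params["rho"]
        return eps, s_rew, s_pun
    gamma = params["gamma"]
    if spec.rp_variant:
        s_rew, s_pun = params["c_rew"], params["c_pun"]
    else:
        s_rew = s_pun = params["c"]
    return gamma, s_rew, s_pun


def _validate_params(spec: ModelSpec, params: dict) -> None:
    first, s_rew, s_pun = _split_sensitivities(spec, params)
    label = "epsilon" if spec.family in ("SA", "DSA") else "gamma"
    if not (np.isfinite(first) and 0.0 <= first <= 1.0):
        raise ParameterError(f"{label} must lie in [0, 1], got {first!r}")
    if not (np.isfinite(s_rew) and np.isfinite(s_pun)) or s_rew < 0 or s_pun < 0:
        raise ParameterError("sensitivities must be finite and non-negative")


def log_likelihood(spec: ModelSpec, params: dict, trials: pd.DataFrame):
    """Sequential choice log-likelihood.

    Sums ``log P(choice_t | history)`` over valid trials; latent state resets
    at each session start. Returns ``(loglik, p_chosen)`` where ``p_chosen``
    holds the per-trial probability assigned to the made choice (NaN on
    invalid trials).
    """
    _validate_params(spec, params)
    arrays = encode_trials(trials)
    first, s_rew, s_pun = _split_sensitivities(spec, params)
    if spec.family in ("SA", "DSA"):
        ll, p_chosen = qlearn_loglik(*arrays, first, s_rew, s_pun, spec.family == "DSA")
    else:
        ll, p_chosen, _, _ = hmm_loglik(*arrays, first, s_rew, s_pun, Q_EMIT)
    if not np.isfinite(ll):
        raise ParameterError(f"non-finite likelihood under params {params!r}")
    return float(ll), p_chosen


def belief_trajectory(params: dict, trials: pd.DataFrame,
                      spec: ModelSpec | None = None) -> pd.DataFrame:
    """Filtered beliefs of the latent-state model over an event table.

    Returns one row per trial with ``b_prior`` (after the transition, before
    the outcome) and ``b_post`` (after the outcome update) for state 1,
    "left is the good side".
    """
    spec = MODELS["HMM-RP" if ("c_rew" in params) else "HMM"] if spec is None else spec
    if spec.family != "HMM":
        raise ValueError("belief trajectories are defined for the HMM family only")
    _validate_params(spec, params)
    gamma, c_rew, c_pun = _split_sensitivities(spec, params)
    _, _, b_prior, b_post = hmm_loglik(*encode_trials(trials), gamma, c_rew, c_pun, Q_EMIT)
    return pd.DataFrame({"b_prior": b_prior, "b_post": b_post}, index=trials.index)


# ---------------------------------------------------------------------------
# generative agents

class QLearningAgent(_task.Agent):
    def __init__(self, eps: float, rho_rew: float, rho_pun: float, double: bool):
        self.eps, self.rho_rew, self.rho_pun, self.double = eps, rho_rew, rho_pun, double
        self.q = np.zeros(2)

    def reset(self) -> None:
        self.q = np.zeros(2)

    def p_left(self, block_type: str) -> float:
        return float(q_action_prob(self.q)[0])

    def update(self, choice: str, outcome: str) -> None:
        c = 0 if choice == "left" else 1
        r = outcome_value(outcome, self.rho_rew, self.rho_pun)
        self.q = (dsa_update if self.double else sa_update)(self.q, c, r, self.eps)


class BeliefAgent(_task.Agent):
    def __init__(self, gamma: float, c_rew: float, c_pun: float, q_emit: float = Q_EMIT):
        self.gamma, self.c_rew, self.c_pun, self.q_emit = gamma, c_rew, c_pun, q_emit
        self.b_post = 0.5
        self._b_prior = 0.5

    def reset(self) -> None:
        self.b_post = 0.5
        self._b_prior = 0.5

    def p_left(self, block_type: str) -> float:
        self._b_prior = hmm_transition(self.b_post, self.gamma)
        return float(self._b_prior)

    def update(self, choice: str, outcome: str) -> None:
        c = 0 if choice == "left" else 1
        self.b_post = hmm_observe(self._b_prior, c, outcome, self.gamma,
                                  self.c_rew, self.c_pun, self.q_emit)

    def on_invalid(self) -> None:
        self.b_post = hmm_transition(self.b_post, self.gamma)


def make_agent(spec: ModelSpec, params: dict) -> _task.Agent:
    _validate_params(spec, params)
    first, s_rew, s_pun = _split_sensitivities(spec, params)
    if spec.family in ("SA", "DSA"):
        return QLearningAgent(first, s_rew, s_pun, spec.family == "DSA")
    return BeliefAgent(first, s_rew, s_pun)


def simulate_agent(spec: ModelSpec, params: dict, config: _task.TaskConfig,
                   seed: int, subject_id: str = "sim") -> pd.DataFrame:
    """Generate surrogate choices by running the model's policy on the task."""
    agent = make_agent(spec, params)
    return _task.simulate_session_frame(agent, config, seed, subject_id)
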