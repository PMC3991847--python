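"""Sequential likelihood kernels, numba-compiled when numba is importable.

Choices are coded 0=left, 1=right; outcomes 1=reward, 0=punishment. Invalid
trials contribute no choice likelihood: Q-values stay untouched, the belief
of the latent-state model still undergoes its transition step. ``new_sess``
marks trials at which latent state resets (session starts).
"""

from __future__ import annotations

import math

import numpy as np

_BELIEF_EPS = 1e-15


def _qlearn_loglik_py(choices, outcomes, valid, new_sess, eps, rho_rew, rho_pun, double):
    n = choices.shape[0]
    p_chosen = np.full(n, np.nan)
    q_left = 0.0
    q_right = 0.0
    loglik = 0.0
    for t in range(n):
        if new_sess[t]:
            q_left = 0.0
            q_right = 0.0
        if not valid[t]:
            continue
        p_l = 1.0 / (1.0 + math.exp(-(q_left - q_right)))
        p = p_l if choices[t] == 0 else 1.0 - p_l
        if p < _BELIEF_EPS:
            p = _BELIEF_EPS
        loglik += math.log(p)
        p_chosen[t] = p
        r = rho_rew if outcomes[t] == 1 else -rho_pun
        if choices[t] == 0:
            q_left += eps * (r - q_left)
            if double:
                q_right += eps * (-r - q_right)
        else:
            q_right += eps * (r - q_right)
            if double:
                q_left += eps * (-r - q_left)
    return loglik, p_chosen


def _hmm_loglik_py(choices, outcomes, valid, new_sess, gamma, c_rew, c_pun, q_emit):
    n = choices.shape[0]
    p_chosen = np.full(n, np.nan)
    b_prior = np.empty(n)
    b_post = np.empty(n)
    d0 = math.log(q_emit / (1.0 - q_emit))
    if gamma < _BELIEF_EPS:
        gamma = _BELIEF_EPS
    elif gamma > 1.0 - _BELIEF_EPS:
        gamma = 1.0 - _BELIEF_EPS
    lam = 0.0  # posterior log-odds of state 1 ("left is the good side")
    loglik = 0.0
    for t in range(n):
        if new_sess[t]:
            lam = 0.0
        b = 1.0 / (1.0 + math.exp(-lam))
        bp = gamma * b + (1.0 - gamma) * (1.0 - b)
        if bp < _BELIEF_EPS:
            bp = _BELIEF_EPS
        elif bp > 1.0 - _BELIEF_EPS:
            bp = 1.0 - _BELIEF_EPS
        b_prior[t] = bp
        lam = math.log(bp / (1.0 - bp))
        if not valid[t]:
            b_post[t] = bp
            continue
        p = bp if choices[t] == 0 else 1.0 - bp
        loglik += math.log(p)
        p_chosen[t] = p
        # (left, reward) and (right, punishment) favor state 1
        sign = 1.0 if (choices[t] == 0) == (outcomes[t] == 1) else -1.0
        w = c_rew if outcomes[t] == 1 else c_pun
        lam += w * sign * d0
        b_post[t] = 1.0 / (1.0 + math.exp(-lam))
    return loglik, p_chosen, b_prior, b_post


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    qlearn_loglik = njit(cache=True)(_qlearn_loglik_py)
    hmm_loglik = njit(cache=True)(_hmm_loglik_py)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    qlearn_loglik = _qlearn_loglik_py
    hmm_loglik = _hmm_loglik_py
    HAVE_NUMBA = False
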