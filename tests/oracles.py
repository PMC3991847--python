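"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's sequential kernels: beliefs are
computed by enumerating latent state paths, and likelihood normalization by
enumerating complete choice sequences.
"""

import itertools

import numpy as np

from tests.conftest import trials_frame


def path_enumeration_beliefs(choices, outcomes, gamma, q=0.8):
    """Filtered two-state beliefs by exhaustive state-path enumeration.

    State 0 = "left is the good side". Emission: reward probability ``q``
    when the choice matches the good side, ``1-q`` otherwise; the state
    prior is uniform and transitions stay with probability ``gamma``.
    Returns (b_prior, b_post) for state 0 at each trial, where b_prior
    conditions on outcomes before the trial and b_post includes the trial's
    outcome.
    """
    T = len(choices)
    b_prior = np.empty(T)
    b_post = np.empty(T)

    def emission(state, choice, outcome):
        p_rew = q if choice == state else 1.0 - q  # choice 0=left matches state 0
        return p_rew if outcome == 1 else 1.0 - p_rew

    for t in range(T):
        marg_prior = np.zeros(2)
        marg_post = np.zeros(2)
        for path in itertools.product((0, 1), repeat=t + 1):
            w = 0.5
            for u in range(1, t + 1):
                w *= gamma if path[u] == path[u - 1] else 1.0 - gamma
            for u in range(t):  # outcomes observed before trial t
                w *= emission(path[u], choices[u], outcomes[u])
            marg_prior[path[t]] += w
            marg_post[path[t]] += w * emission(path[t], choices[t], outcomes[t])
        b_prior[t] = marg_prior[0] / marg_prior.sum()
        b_post[t] = marg_post[0] / marg_post.sum()
    return b_prior, b_post


def enumerate_choice_probability_mass(spec, params, outcome_table, log_likelihood):
    """Total probability of all 2^T choice sequences under fixed outcome maps.

    ``outcome_table[t, c]`` gives the outcome (1=reward) delivered if choice
    ``c`` is made on trial ``t``; this makes the outcome a deterministic
    function of the choice history so the per-sequence likelihoods must sum
    to one for any properly normalized sequential choice model.
    """
    T = outcome_table.shape[0]
    total = 0.0
    for seq in itertools.product((0, 1), repeat=T):
        df = trials_frame(seq, [outcome_table[t, c] for t, c in enumerate(seq)])
        ll, _ = log_likelihood(spec, params, df)
        total += np.exp(ll)
    return total


def gauss_hermite_integrated_bic(spec, prior, events, log_likelihood,
                                 split_subjects, n_nodes=40):
    """Integrated BIC by tensor-product Gauss-Hermite quadrature (k <= 2)."""
    from revlearn.fitting import untransform

    k = spec.n_params
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    grids = np.meshgrid(*[nodes] * k, indexing="ij")
    wgrids = np.meshgrid(*[weights] * k, indexing="ij")
    w = np.ones_like(wgrids[0])
    for wg in wgrids:
        w = w * wg
    w = w.ravel() / (2 * np.pi) ** (k / 2)
    thetas = np.stack([prior.mu[i] + np.sqrt(prior.sigma2[i]) * grids[i].ravel()
                       for i in range(k)], axis=1)

    total = 0.0
    n_choices = 0
    for trials in split_subjects(events).values():
        like = np.array([
            np.exp(log_likelihood(spec, untransform(th, spec), trials)[0])
            for th in thetas
        ])
        total += np.log(np.sum(w * like))
        n_choices += int(trials["valid"].sum())
    return -2.0 * total + 2 * k * np.log(n_choices)
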