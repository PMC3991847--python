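"""Group-level model comparison by integrated BIC.

For each candidate, the cohort marginal likelihood is estimated by Monte
Carlo: subject likelihoods are averaged over parameter draws from the fitted
group prior. The score is

    BIC_int = -2 * sum_i log( (1/m) sum_j p(choices_i | theta_j) )
              + n_group_params * log(total valid choices)

with ``n_group_params = 2k`` (a mean and a variance per model parameter).
Lower is better; the winner has ``delta BIC_int = 0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._kernels import hmm_loglik, qlearn_loglik
from .fitting import GroupFitResult, GroupPrior, fit_group_em, split_subjects, untransform
from .models import Q_EMIT, ModelSpec, _split_sensitivities, encode_trials, get_model

logger = logging.getLogger(__name__)

#: default "random effects" line: Bayes factor of 20 on the deviance scale
DEFAULT_THRESHOLD = 2.0 * math.log(20.0)


def integrated_bic(
    spec: ModelSpec,
    prior: GroupPrior,
    events: pd.DataFrame,
    n_samples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo integrated BIC and its Monte-Carlo standard error."""
    if n_samples < 100:
        logger.warning("n_samples=%d is small; the BIC_int estimate may be unstable",
                       n_samples)
    rng = np.random.default_rng(seed)
    cohort = split_subjects(events)
    k = spec.n_params
    thetas = prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal((n_samples, k))
    draws = [_split_sensitivities(spec, untransform(thetas[j], spec))
             for j in range(n_samples)]
    is_q = spec.family in ("SA", "DSA")
    is_double = spec.family == "DSA"

    total_log = 0.0
    var_sum = 0.0
    n_choices = 0
    for trials in cohort.values():
        arrays = encode_trials(trials)
        lls = np.empty(n_samples)
        for j, (first, s_rew, s_pun) in enumerate(draws):
            if is_q:
                lls[j], _ = qlearn_loglik(*arrays, first, s_rew, s_pun, is_double)
            else:
                lls[j], _, _, _ = hmm_loglik(*arrays, first, s_rew, s_pun, Q_EMIT)
        log_mean = logsumexp(lls) - np.log(n_samples)
        total_log += log_mean
        # delta-method SE of log-mean from the normalized weights
        w = np.exp(lls - lls.max())
        var_sum += np.var(w, ddof=1) / (n_samples * np.mean(w) ** 2)
        n_choices += int(trials["valid"].sum())

    penalty = 2 * k * np.log(max(n_choices, 1))
    bic = -2.0 * total_log + penalty
    mc_se = 2.0 * math.sqrt(var_sum)
    return float(bic), float(mc_se)


@dataclass
class ComparisonResult:
    table: pd.DataFrame            # per model: bic_int, delta_bic_int, mc_se, ...
    best_model: str
    threshold: float = DEFAULT_THRESHOLD
    group_fits: dict = field(default_factory=dict)  # name -> GroupFitResult

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string(index=False)


def compare_models(
    model_names: list,
    events: pd.DataFrame,
    n_samples: int = 2000,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    em_kwargs: dict | None = None,
) -> ComparisonResult:
    """Fit each candidate with group EM, score by BIC_int, and rank.

    Models whose group fit raises are excluded with a logged reason. Ties in
    BIC_int are broken in favor of the model with fewer parameters.
    """
    if not model_names:
        raise ValueError("need at least one candidate model")
    em_kwargs = dict(em_kwargs or {})
    rows = []
    group_fits: dict[str, GroupFitResult] = {}
    for name in model_names:
        spec = get_model(name)
        try:
            gf = fit_group_em(spec, events, seed=seed, **em_kwargs)
            bic, mc_se = integrated_bic(spec, gf.prior, events,
                                        n_samples=n_samples, seed=seed + 1)
        except Exception:
            logger.exception("model %s excluded from comparison", name)
            continue
        group_fits[name] = gf
        rows.append({"model": name, "bic_int": bic, "mc_se": mc_se,
                     "n_params": spec.n_params, "n_group_params": 2 * spec.n_params,
                     "em_converged": gf.converged})
    if not rows:
        raise RuntimeError("every candidate model failed to fit")

    table = pd.DataFrame(rows)
    order = np.lexsort((table["n_params"].to_numpy(), table["bic_int"].to_numpy()))
    best = str(table.iloc[order[0]]["model"])
    table["delta_bic_int"] = table["bic_int"] - float(table["bic_int"].min())
    table = table.iloc[order].reset_index(drop=True)
    table["above_threshold"] = table["delta_bic_int"] > threshold
    return ComparisonResult(table, best, threshold, group_fits)
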