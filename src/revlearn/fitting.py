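"""Hierarchical random-effects fitting.

Subjects are fitted by MAP estimation in an unconstrained (transformed)
parameter space under a diagonal Gaussian group prior. The group prior is
itself estimated by expectation-maximization: the E-step computes each
subject's posterior mode and a Laplace (curvature-based) covariance, the
M-step re-estimates the prior mean and variance from the subject posteriors.
A per-subject better-than-chance test (binomial on the number of choices
predicted above 0.5) flags subjects the model does not capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from ._kernels import hmm_loglik, qlearn_loglik
from .models import Q_EMIT, ModelSpec, _split_sensitivities, encode_trials

logger = logging.getLogger(__name__)

_SIGMA2_FLOOR = 1e-6
_HESS_STEP = 1e-4


def transform(params: dict, spec: ModelSpec) -> np.ndarray:
    """Map natural-scale parameters to the unconstrained fitting space."""
    out = np.empty(spec.n_params)
    for i, (name, tr) in enumerate(zip(spec.parameter_names, spec.transforms)):
        v = float(params[name])
        if tr == "logit":
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
            out[i] = logit(v)
        elif tr == "log":
            if v <= 0.0:
                raise ValueError(f"{name}={v} outside (0, inf)")
            out[i] = np.log(v)
        else:
            out[i] = v
    return out


def untransform(theta: np.ndarray, spec: ModelSpec) -> dict:
    """Inverse of :func:`transform`."""
    params = {}
    for i, (name, tr) in enumerate(zip(spec.parameter_names, spec.transforms)):
        x = float(theta[i])
        if tr == "logit":
            params[name] = float(expit(x))
        elif tr == "log":
            params[name] = float(np.exp(x))
        else:
            params[name] = x
    return params


@dataclass
class GroupPrior:
    """Diagonal Gaussian prior on the transformed parameters."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(self.sigma2 <= 0):
            raise ValueError("prior variances must be positive")

    def logpdf(self, theta: np.ndarray) -> float:
        z2 = (theta - self.mu) ** 2 / self.sigma2
        return float(-0.5 * np.sum(z2 + np.log(2 * np.pi * self.sigma2)))


def default_prior(spec: ModelSpec, scale: float = 2.0) -> GroupPrior:
    """Vague prior centred on the transform origin (eps=0.5, rho=c=1, gamma=0.5)."""
    k = spec.n_params
    return GroupPrior(np.zeros(k), np.full(k, scale**2))


@dataclass
class SubjectFit:
    subject_id: str
    theta: np.ndarray                  # MAP in transformed space
    params: dict                       # MAP on the natural scale
    hessian: np.ndarray                # curvature of -log posterior at theta
    loglik: float                      # data log-likelihood at theta
    log_posterior: float               # loglik + log prior at theta
    n_valid_trials: int
    predictive_probability: float      # mean per-trial P(made choice)
    n_above_half: int                  # trials with P(made choice) > 0.5
    good_fit: bool = False
    p_chance: float = 1.0
    converged: bool = True

    @property
    def laplace_var(self) -> np.ndarray:
        """Diagonal of the inverse curvature (subject posterior variance)."""
        try:
            cov = np.linalg.inv(self.hessian)
            var = np.diag(cov).copy()
        except np.linalg.LinAlgError:
            var = 1.0 / np.maximum(np.diag(self.hessian), _SIGMA2_FLOOR)
        return np.maximum(var, _SIGMA2_FLOOR)


def _kernel_loglik(spec: ModelSpec, arrays, theta: np.ndarray):
    """Likelihood of pre-encoded trials at a transformed-space point."""
    with np.errstate(over="ignore"):
        first, s_rew, s_pun = _split_sensitivities(spec, untransform(theta, spec))
    if not (np.isfinite(s_rew) and np.isfinite(s_pun)):
        return -np.inf, None
    if spec.family in ("SA", "DSA"):
        ll, p_chosen = qlearn_loglik(*arrays, first, s_rew, s_pun, spec.family == "DSA")
    else:
        ll, p_chosen, _, _ = hmm_loglik(*arrays, first, s_rew, s_pun, Q_EMIT)
    return ll, p_chosen


def _make_objective(spec: ModelSpec, trials: pd.DataFrame, prior: GroupPrior):
    arrays = encode_trials(trials)

    def obj(theta: np.ndarray) -> float:
        ll, _ = _kernel_loglik(spec, arrays, theta)
        lp = ll + prior.logpdf(theta)
        return -lp if np.isfinite(lp) else 1e12

    return obj, arrays


def _fd_hessian(f, x: np.ndarray, step: float = _HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = x.size
    h = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step
        h[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return h


def _ensure_pd(h: np.ndarray) -> np.ndarray:
    """Shift eigenvalues so the curvature is usable as a precision matrix."""
    h = 0.5 * (h + h.T)
    w = np.linalg.eigvalsh(h)
    if w.min() <= _SIGMA2_FLOOR:
        h = h + (abs(w.min()) + 1e-3) * np.eye(h.shape[0])
    return h


def fit_subject_map(
    spec: ModelSpec,
    trials: pd.DataFrame,
    prior: GroupPrior,
    restarts: int = 10,
    seed: int = 0,
    x0: np.ndarray | None = None,
    alpha: float = 0.05,
) -> SubjectFit:
    """MAP estimate of one subject's parameters under the group prior.

    Optimizes log-likelihood + log-prior in the transformed space from the
    prior mean plus ``restarts - 1`` perturbed starts (and ``x0`` when given,
    e.g. a warm start from a previous EM iteration). Non-convergence of every
    start flags the result rather than raising.
    """
    rng = np.random.default_rng(seed)
    k = spec.n_params
    starts = [prior.mu.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    while len(starts) < max(restarts, 1) + (x0 is not None):
        starts.append(prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal(k))

    obj, arrays = _make_objective(spec, trials, prior)
    best = None
    any_converged = False
    for s in starts:
        res = optimize.minimize(obj, s, method="L-BFGS-B")
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    params = untransform(theta, spec)
    ll, p_chosen = _kernel_loglik(spec, arrays, theta)
    if p_chosen is None:
        p_chosen = np.full(len(trials), np.nan)
    hess = _ensure_pd(_fd_hessian(obj, theta))
    pc = p_chosen[np.isfinite(p_chosen)]
    n_valid = int(pc.size)
    fit = SubjectFit(
        subject_id=str(trials["subject_id"].iloc[0]) if len(trials) else "",
        theta=theta,
        params=params,
        hessian=hess,
        loglik=ll,
        log_posterior=ll + prior.logpdf(theta),
        n_valid_trials=n_valid,
        predictive_probability=float(pc.mean()) if n_valid else 0.5,
        n_above_half=int(np.sum(pc > 0.5)),
        converged=any_converged,
    )
    chance_fit_test(fit, alpha=alpha)
    return fit


def chance_fit_test(fit: SubjectFit, alpha: float = 0.05,
                    method: str = "binomial", pp_threshold: float = 0.5) -> SubjectFit:
    """Classify a fitted subject as captured better than chance.

    ``binomial`` (default): one-sided binomial test on the number of valid
    trials whose made choice received probability > 0.5. ``mean_pp``: simple
    threshold on the mean predictive probability.
    """
    if method == "binomial":
        if fit.n_valid_trials == 0:
            fit.p_chance, fit.good_fit = 1.0, False
            return fit
        test = stats.binomtest(fit.n_above_half, fit.n_valid_trials, 0.5,
                               alternative="greater")
        fit.p_chance = float(test.pvalue)
        fit.good_fit = fit.p_chance < alpha
    elif method == "mean_pp":
        fit.p_chance = float("nan")
        fit.good_fit = fit.predictive_probability > pp_threshold
    else:
        raise ValueError(f"unknown chance-test method {method!r}")
    return fit


@dataclass
class GroupFitResult:
    prior: GroupPrior
    subject_fits: list
    marginal_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def fits_by_subject(self) -> dict:
        return {f.subject_id: f for f in self.subject_fits}


def _approx_marginal(fits: list, k: int) -> float:
    """Laplace approximation of the summed log marginal likelihood."""
    total = 0.0
    for f in fits:
        sign, logdet = np.linalg.slogdet(f.hessian)
        logdet = logdet if sign > 0 else np.sum(np.log(np.diag(f.hessian)))
        total += f.log_posterior + 0.5 * k * np.log(2 * np.pi) - 0.5 * logdet
    return float(total)


def split_subjects(events: pd.DataFrame) -> dict:
    """Per-subject event tables, preserving trial order within subject."""
    return {sid: df.reset_index(drop=True) for sid, df in events.groupby("subject_id", sort=True)}


def fit_group_em(
    spec: ModelSpec,
    events: pd.DataFrame,
    init: GroupPrior | None = None,
    max_iter: int = 40,
    tol: float = 1e-3,
    restarts: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupFitResult:
    """Empirical-Bayes EM over a cohort event table.

    E-step: per-subject MAP plus Laplace covariance under the current prior
    (warm-started from the previous iteration's modes). M-step: prior mean is
    the average posterior mode; prior variance the average of squared
    deviations plus Laplace variances, floored at a small constant.
    Iterates until the Laplace-approximate marginal likelihood improves by
    less than ``tol``.
    """
    cohort = split_subjects(events)
    if len(cohort) < 2:
        raise ValueError("group fitting needs at least 2 subjects")
    prior = default_prior(spec) if init is None else init
    k = spec.n_params

    warm: dict = {}
    trace: list = []
    fits: list = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fits = [
            fit_subject_map(spec, trials, prior,
                            restarts=restarts if it == 1 else 1,
                            seed=seed + 7919 * i, x0=warm.get(sid), alpha=alpha)
            for i, (sid, trials) in enumerate(cohort.items())
        ]
        warm = {f.subject_id: f.theta for f in fits}

        thetas = np.array([f.theta for f in fits])
        lap_vars = np.array([f.laplace_var for f in fits])
        mu = thetas.mean(axis=0)
        sigma2 = ((thetas - mu) ** 2 + lap_vars).mean(axis=0)
        if np.any(sigma2 < _SIGMA2_FLOOR):
            logger.warning("group variance floored at %g for %s", _SIGMA2_FLOOR, spec.name)
            sigma2 = np.maximum(sigma2, _SIGMA2_FLOOR)
        prior = GroupPrior(mu, sigma2)

        trace.append(_approx_marginal(fits, k))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return GroupFitResult(prior, fits, trace, n_iter=it, converged=converged)


def fits_to_frame(fits: list, spec: ModelSpec) -> pd.DataFrame:
    """Flat per-subject fit table for export."""
    rows = []
    for f in fits:
        row = {"subject_id": f.subject_id, "loglik": f.loglik,
               "n_valid_trials": f.n_valid_trials,
               "predictive_probability": f.predictive_probability,
               "n_above_half": f.n_above_half,
               "good_fit": f.good_fit, "p_chance": f.p_chance,
               "converged": f.converged}
        for name in spec.parameter_names:
            row[name] = f.params[name]
        rows.append(row)
    return pd.DataFrame(rows)
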