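"""Posterior sampling of agent parameters and Bayesian model selection.

Model fitting uses adaptive random-walk Metropolis–Hastings (four chains,
early stopping on the Gelman–Rubin diagnostic).  Model comparison follows
the session-level cross-validation scheme: for each subject, hold out one
session, sample the posterior over parameters from the held-in sessions,
and estimate the held-out marginal likelihood as a Monte-Carlo average of
the held-out likelihood over posterior samples.  Subject-level log
marginal likelihoods feed a random-effects Bayesian model selection: a
variational Dirichlet model over model frequencies in the population, with
exceedance probabilities estimated by Monte-Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, logsumexp

from .agents import AgentParams, action_loglik

# uniform prior boxes per parameter (weakly informative, reproducible)
PARAM_BOUNDS = {
    "alpha": (1e-3, 1.0),
    "sigma_c": (1e-3, 2.0),
    "lapse_left": (0.0, 0.499),
    "lapse_right": (0.0, 0.499),
}


def model_param_names(kind: str) -> list[str]:
    names = ["sigma_c", "lapse_left", "lapse_right"]
    if kind in ("action_kernel", "stimulus_kernel"):
        names = ["alpha"] + names
    return names


def make_params(kind: str, theta: np.ndarray, policy: str = "probability_matching") -> AgentParams:
    kwargs = dict(zip(model_param_names(kind), theta))
    return AgentParams(kind=kind, policy=policy, **kwargs)


def sessions_loglik(sessions, kind: str, theta: np.ndarray,
                    traces: list | None = None) -> float:
    """Total log-likelihood of the recorded choices across sessions.

    ``traces`` optionally carries precomputed prior traces (worthwhile for
    the Bayes-optimal model, whose trace does not depend on θ).
    """
    try:
        params = make_params(kind, theta)
    except ValueError:
        return -np.inf
    total = 0.0
    for i, sess in enumerate(sessions):
        tr = traces[i] if traces is not None else None
        ll = action_loglik(sess, params, trace=tr)
        total += np.nansum(ll)
    return float(total)


def _prepare_sessions(sessions, kind: str) -> list[dict]:
    """Strip sessions to numeric arrays so the sampler never touches pandas."""
    from .agents import _encode_sides, prior_trace_for

    prepped = []
    for sess in sessions:
        choices = _encode_sides(sess["choice"].to_numpy())
        entry = {
            "contrasts": sess["signed_contrast"].to_numpy(dtype=float),
            "choices": choices,
            "included": sess["included"].to_numpy(dtype=bool) & (choices >= 0),
        }
        if kind in ("bayes_optimal", "true_block"):
            probe = AgentParams(kind=kind)
            entry["trace"] = prior_trace_for(sess, probe).values
        elif kind == "stimulus_kernel":
            entry["events"] = _encode_sides(sess["stim_side"].to_numpy())
        else:
            entry["events"] = choices
        prepped.append(entry)
    return prepped


def _prepared_loglik(prepped: list[dict], kind: str, theta: np.ndarray) -> float:
    from .agents import kernel_prior, trial_choice_prob

    try:
        params = make_params(kind, theta)
    except ValueError:
        return -np.inf
    total = 0.0
    for e in prepped:
        if "trace" in e:
            trace = e["trace"]
        else:
            trace = kernel_prior(e["events"], params.alpha, params.pi_init).values
        p_r = trial_choice_prob(trace, e["contrasts"], params)
        p_choice = np.where(e["choices"] == 1, p_r, 1.0 - p_r)
        ll = np.log(np.clip(p_choice[e["included"]], 1e-300, None))
        total += float(ll.sum())
    return total


@dataclass
class MHResult:
    """Adaptive Metropolis–Hastings output."""

    samples: np.ndarray          # (n_chains, n_kept, n_params)
    acceptance_rates: np.ndarray
    gelman_rubin: np.ndarray     # per parameter, on the kept halves
    burn_in: int
    n_steps: int
    param_names: list[str]

    @property
    def n_kept(self) -> int:
        return self.samples.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.samples.reshape(-1, self.samples.shape[-1])


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains`` has shape (n_chains, n_steps, n_params).  Uses the
    between/within variance form: R = sqrt(((n-1)/n · W + B/n) / W).
    Identical chains give exactly 1; chains with disjoint supports blow up.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[..., None]
    m, n, _ = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 2:
        raise ValueError("Gelman-Rubin requires chains of length >= 2")
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.sqrt(var_hat / W)
    # the shrinkage term makes R slightly < 1 for perfectly mixed chains;
    # clamp since values below 1 carry no diagnostic meaning
    return np.where(W > 0, np.maximum(R, 1.0), 1.0)


def adaptive_mh(
    loglik_fn,
    bounds: list[tuple[float, float]],
    seed: int,
    n_chains: int = 4,
    max_steps: int = 5000,
    min_steps: int = 1000,
    check_every: int = 250,
    gr_threshold: float = 1.1,
    param_names: list[str] | None = None,
) -> MHResult:
    """Adaptive random-walk Metropolis–Hastings over a box.

    Gaussian proposals whose covariance is adapted to the empirical sample
    covariance (scaled 2.38²/d) during the adaptation phase (first
    ``min_steps``//2 steps), then frozen so the kept samples come from a
    fixed kernel.  Chains stop early once every parameter's Gelman–Rubin
    statistic (on the second halves) is below ``gr_threshold``, never
    before ``min_steps``.  The first half of each chain is discarded as
    burn-in.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    d = len(bounds)
    adapt_until = min_steps // 2

    states = lo + (hi - lo) * rng.random((n_chains, d))
    logps = np.array([loglik_fn(s) for s in states])
    for c in range(n_chains):  # re-draw starts that land on -inf
        tries = 0
        while not np.isfinite(logps[c]):
            states[c] = lo + (hi - lo) * rng.random(d)
            logps[c] = loglik_fn(states[c])
            tries += 1
            if tries > 100:
                raise RuntimeError("could not find a finite-likelihood start")

    scale = 2.38**2 / d
    cov = np.diag(((hi - lo) / 50.0) ** 2)
    chol = np.linalg.cholesky(cov * scale)
    history = [[s.copy()] for s in states]
    accepted = np.zeros(n_chains)
    recent_acc = 0.0
    recent_n = 0

    step = 0
    while step < max_steps:
        step += 1
        for c in range(n_chains):
            prop = states[c] + chol @ rng.standard_normal(d)
            if np.any(prop < lo) or np.any(prop > hi):
                lp = -np.inf
            else:
                lp = loglik_fn(prop)
            if np.log(rng.random()) < lp - logps[c]:
                states[c] = prop
                logps[c] = lp
                accepted[c] += 1
                recent_acc += 1
            recent_n += 1
            history[c].append(states[c].copy())
        if step <= adapt_until and step % 50 == 0:
            # Haario-style: empirical covariance of the recent halves plus
            # an acceptance-rate correction toward ~0.3
            pooled = np.concatenate(
                [np.asarray(h)[len(h) // 2:] for h in history]
            )
            emp = np.cov(pooled.T).reshape(d, d) + 1e-10 * np.eye(d)
            rate = recent_acc / max(recent_n, 1)
            scale *= np.exp(rate - 0.3)
            chol = np.linalg.cholesky(emp * scale)
            recent_acc = recent_n = 0
        if step >= min_steps and step % check_every == 0:
            chains = np.stack([np.asarray(h)[step // 2:] for h in history])
            if np.all(gelman_rubin(chains) < gr_threshold):
                break

    chains_full = np.stack([np.asarray(h) for h in history])
    burn = chains_full.shape[1] // 2
    kept = chains_full[:, burn:, :]
    return MHResult(
        samples=kept,
        acceptance_rates=accepted / step,
        gelman_rubin=gelman_rubin(kept),
        burn_in=burn,
        n_steps=step,
        param_names=param_names or [f"p{i}" for i in range(d)],
    )


def fit_model_mh(sessions, kind: str, seed: int, **mh_kwargs) -> MHResult:
    """Posterior over a model's parameters given one or more sessions."""
    names = model_param_names(kind)
    bounds = [PARAM_BOUNDS[n] for n in names]
    prepped = _prepare_sessions(sessions, kind)
    return adaptive_mh(
        lambda th: _prepared_loglik(prepped, kind, th),
        bounds, seed=seed, param_names=names, **mh_kwargs,
    )


def fit_model_map(sessions, kind: str, seed: int = 0, n_restarts: int = 5) -> AgentParams:
    """Fast maximum-likelihood point fit (used inside null pipelines)."""
    names = model_param_names(kind)
    bounds = [PARAM_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)
    prepped = _prepare_sessions(sessions, kind)
    best = None
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(*b) for b in bounds])
        res = minimize(
            lambda th: -_prepared_loglik(prepped, kind, th),
            x0, method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    return make_params(kind, best.x)


def heldout_log_marginal(samples: MHResult | np.ndarray, heldout_loglik_fn,
                         max_samples: int | None = 2000) -> float:
    """log of the posterior-sample mean of the held-out likelihood.

    ``log (1/N · Σ_n p(A_heldout | θ_n))`` via log-sum-exp; the mean of
    likelihoods (not of log-likelihoods) is the Monte-Carlo estimate of
    the held-out marginal likelihood.  Long chains are thinned evenly to
    ``max_samples`` draws.
    """
    theta = samples.flat if isinstance(samples, MHResult) else np.atleast_2d(samples)
    if max_samples is not None and len(theta) > max_samples:
        idx = np.linspace(0, len(theta) - 1, max_samples).astype(int)
        theta = theta[idx]
    lls = np.array([heldout_loglik_fn(th) for th in theta])
    if np.all(np.isneginf(lls)):
        import warnings

        warnings.warn("held-out likelihood is zero for every posterior sample")
        return -np.inf
    return float(logsumexp(lls) - np.log(len(lls)))


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection output."""

    frequencies: np.ndarray
    exceedance: np.ndarray
    alpha: np.ndarray
    lme: np.ndarray
    models: list[str]


def bms(lme: np.ndarray, seed: int = 0, alpha0: float = 1.0,
        models: list[str] | None = None, n_mc: int = 100_000,
        max_iter: int = 10_000, tol: float = 1e-8) -> BMSResult:
    """Variational random-effects model selection over subjects × models.

    Fits a Dirichlet population distribution over model identities
    (uniform concentration ``alpha0``): iterate
    ``u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))``, ``α = α0 + Σ_n u_nk``.
    Model frequencies are the Dirichlet mean; exceedance probabilities are
    estimated by sampling the fitted Dirichlet.
    """
    lme = np.asarray(lme, dtype=float)
    n_sub, n_mod = lme.shape
    if n_mod < 2:
        raise ValueError("model selection needs at least 2 models")
    bad = np.all(np.isneginf(lme) | np.isnan(lme), axis=1)
    if bad.any():
        raise ValueError(
            f"subject {int(np.flatnonzero(bad)[0])} has no finite log evidence"
        )
    alpha = np.full(n_mod, alpha0)
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc)
    exceedance = np.bincount(draws.argmax(axis=1), minlength=n_mod) / n_mc
    return BMSResult(
        frequencies=alpha / alpha.sum(),
        exceedance=exceedance,
        alpha=alpha,
        lme=lme,
        models=models or [f"m{k}" for k in range(n_mod)],
    )


def subject_log_marginal(sessions, kind: str, seed: int, **mh_kwargs) -> float:
    """Leave-one-session-out log marginal likelihood for one subject.

    Sessions are held out one at a time; the model is sampled on the
    held-in sessions and the held-out marginal likelihood is accumulated.
    Subjects need at least two sessions.
    """
    if len(sessions) < 2:
        raise ValueError("session-wise cross-validation needs >= 2 sessions")
    total = 0.0
    for i in range(len(sessions)):
        held_in = [s for j, s in enumerate(sessions) if j != i]
        mh = fit_model_mh(held_in, kind, seed=seed + i, **mh_kwargs)
        prepped = _prepare_sessions([sessions[i]], kind)
        total += heldout_log_marginal(
            mh, lambda th: _prepared_loglik(prepped, kind, th)
        )
    return total


def model_comparison(
    subjects: dict[str, list[pd.DataFrame]],
    kinds: list[str],
    seed: int = 0,
    **mh_kwargs,
) -> BMSResult:
    """Full pipeline: per-subject LOSO evidences, then Bayesian selection."""
    names = list(subjects)
    lme = np.zeros((len(names), len(kinds)))
    for i, name in enumerate(names):
        for k, kind in enumerate(kinds):
            lme[i, k] = subject_log_marginal(
                subjects[name], kind, seed=seed + 1000 * i + 100 * k, **mh_kwargs
            )
    return bms(lme, seed=seed, models=kinds)
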