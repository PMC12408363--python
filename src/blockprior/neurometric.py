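"""Prior-conditioned neurometric curves from a signed-contrast decoder.

To detect a prior signal in post-stimulus activity without confounding it
with the (prior-correlated) stimulus, a linear decoder is first trained
on the signed contrast.  Its held-out output ŝ is then summarized as the
proportion of trials decoded "right" (ŝ > 0) per contrast level,
separately for trials with a low (< 0.5) or high (> 0.5) Bayes-optimal
prior.  Both proportions are fitted jointly with an erf psychometric
model with shared lapse and slope parameters and condition-specific bias:

    f(c) = γ + (1 - γ - λ) · (erf((c - μ) / σ) + 1) / 2

The neurometric shift, f_high(0) − f_low(0), measures prior encoding
beyond the stimulus; its null distribution comes from decoding
pseudo-contrast sequences from the same activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf

from .decoding import DecodeSpec, nested_cv_decode, signed_contrast_target, \
    bayes_prior_target
from .taskgen import generate_pseudosessions

LAPSE_MAX = 0.3
SIGMA_BOUNDS = (0.01, 2.0)
MU_BOUNDS = (-0.5, 0.5)


@dataclass
class NeurometricFit:
    """Joint erf fit of the low/high-prior neurometric curves."""

    gamma: float            # low lapse rate
    lam: float              # high lapse rate
    sigma: float            # slope (rate of change)
    mu_low: float
    mu_high: float
    shift: float            # f_high(0) - f_low(0)
    shared: bool
    loglik: float
    bic: float
    n_obs: int
    # independent-parameter variant stores per-condition (gamma, lam, sigma)
    extras: dict | None = None


def erf_curve(c, gamma, lam, mu, sigma):
    return gamma + (1.0 - gamma - lam) * (erf((np.asarray(c, float) - mu) / sigma) + 1.0) / 2.0


def decode_signed_contrast(X, contrasts, spec: DecodeSpec | None = None,
                           seed: int = 0) -> np.ndarray:
    """Held-out continuous estimate ŝ of the signed contrast per trial."""
    spec = spec or DecodeSpec(grid=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0))
    return nested_cv_decode(X, np.asarray(contrasts, float), spec, seed=seed).predictions


def _condition_proportions(s_hat, contrasts, prior):
    """(c, k_right, n) per contrast for prior < 0.5 and > 0.5 conditions."""
    s_hat = np.asarray(s_hat, float)
    c = np.asarray(contrasts, float)
    p = np.asarray(prior, float)
    out = {}
    for name, mask in (("low", p < 0.5), ("high", p > 0.5)):
        levels = np.unique(c[mask])
        k = np.array([(s_hat[mask & (c == lv)] > 0).sum() for lv in levels])
        n = np.array([(mask & (c == lv)).sum() for lv in levels])
        out[name] = (levels, k, n)
    return out


def _binom_nll(params_by_cond, props):
    nll = 0.0
    for name, (levels, k, n) in props.items():
        gamma, lam, mu, sigma = params_by_cond[name]
        f = np.clip(erf_curve(levels, gamma, lam, mu, sigma), 1e-9, 1 - 1e-9)
        nll -= float(np.sum(k * np.log(f) + (n - k) * np.log(1 - f)))
    return nll


def neurometric_fit(s_hat, contrasts, prior, shared: bool = True,
                    n_restarts: int = 10, seed: int = 0) -> NeurometricFit:
    """Binomial maximum-likelihood erf fit of the two prior conditions.

    With ``shared=True`` the lapses γ, λ and slope σ are common and only
    the bias μ differs between conditions (5 parameters); otherwise all
    four parameters are free per condition (8 parameters).  Trials with
    prior exactly 0.5 belong to neither condition.
    """
    props = _condition_proportions(s_hat, contrasts, prior)
    for name, (levels, _, n) in props.items():
        if (n > 0).sum() < 2:
            raise ValueError(f"{name}-prior condition has fewer than 2 contrast levels")

    rng = np.random.default_rng(seed)
    if shared:
        # theta = (gamma, lam, sigma, mu_low, mu_high)
        bounds = [(0, LAPSE_MAX), (0, LAPSE_MAX), SIGMA_BOUNDS, MU_BOUNDS, MU_BOUNDS]

        def unpack(th):
            g, l, s, ml, mh = th
            return {"low": (g, l, ml, s), "high": (g, l, mh, s)}
    else:
        # theta = (gamma, lam, sigma, mu) per condition
        bounds = [(0, LAPSE_MAX), (0, LAPSE_MAX), SIGMA_BOUNDS, MU_BOUNDS] * 2

        def unpack(th):
            return {"low": (th[0], th[1], th[3], th[2]),
                    "high": (th[4], th[5], th[7], th[6])}

    def nll(th):
        return _binom_nll(unpack(th), props)

    best = None
    starts = [np.array([0.05, 0.05, 0.2, -0.05, 0.05] if shared
                       else [0.05, 0.05, 0.2, -0.05, 0.05, 0.05, 0.2, 0.05])]
    for _ in range(n_restarts - 1):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    th = best.x
    pb = unpack(th)
    ll = -best.fun
    n_obs = int(sum(n.sum() for _, _, n in props.values()))
    k_par = len(bounds)
    bic = k_par * np.log(max(n_obs, 1)) - 2.0 * ll
    f0 = {name: float(erf_curve(0.0, *pb[name])) for name in ("low", "high")}
    g_lo, l_lo, mu_lo, s_lo = pb["low"]
    g_hi, l_hi, mu_hi, s_hi = pb["high"]
    return NeurometricFit(
        gamma=float(g_lo), lam=float(l_lo), sigma=float(s_lo),
        mu_low=float(mu_lo), mu_high=float(mu_hi),
        shift=f0["high"] - f0["low"],
        shared=shared, loglik=float(ll), bic=float(bic), n_obs=n_obs,
        extras=None if shared else {"high": (g_hi, l_hi, s_hi)},
    )


def bic_shared_vs_independent(s_hat, contrasts, prior, seed: int = 0) -> float:
    """ΔBIC = BIC(independent parameters) − BIC(shared); > 0 favours shared."""
    shared = neurometric_fit(s_hat, contrasts, prior, shared=True, seed=seed)
    indep = neurometric_fit(s_hat, contrasts, prior, shared=False, seed=seed)
    return float(indep.bic - shared.bic)


def neurometric_significance(
    X,
    session: pd.DataFrame,
    spec: DecodeSpec | None = None,
    M: int = 200,
    seed: int = 0,
    n_restarts: int = 4,
) -> dict:
    """Pseudosession p-value for the neurometric shift.

    The actual shift comes from decoding the real signed contrasts.  Each
    null draw decodes a pseudosession's contrast sequence from the same
    activity and fits curves conditioned on that pseudosession's
    Bayes-optimal prior; the p-value is the actual shift's quantile.
    """
    spec = spec or DecodeSpec(grid=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0))
    contrasts = signed_contrast_target(session)
    prior = bayes_prior_target(session)
    s_hat = nested_cv_decode(X, contrasts, spec, seed=seed).predictions
    fit = neurometric_fit(s_hat, contrasts, prior, seed=seed)

    pseudos = generate_pseudosessions(session, M, seed=seed)
    null = np.full(M, np.nan)
    for i, ps in enumerate(pseudos):
        ps_c = signed_contrast_target(ps)
        ps_prior = bayes_prior_target(ps, pseudos.config)
        ps_hat = nested_cv_decode(X, ps_c, spec, seed=seed).predictions
        try:
            null[i] = neurometric_fit(ps_hat, ps_c, ps_prior, seed=seed,
                                      n_restarts=n_restarts).shift
        except ValueError:
            continue
    ok = np.isfinite(null)
    p = (1.0 + np.sum(null[ok] >= fit.shift)) / (ok.sum() + 1.0)
    return {"fit": fit, "shift": fit.shift, "null_shifts": null[ok],
            "p_value": float(p)}
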