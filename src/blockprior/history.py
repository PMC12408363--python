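"""History dependence of the decoded prior and neural timescales.

Three complementary probes of whether neural prior signals carry the
*animal's* (action-integrating) history rather than the ideal observer's:

* **stepwise orthogonalization** — regress the decoded prior on the
  previous action, the residual on the action before that, and so on up
  to lag K, yielding one weight per lag; significance against
  pseudo-weights from simulated (synthetic-session) behaviour.
* **neural-agent asymmetry** — a hypothetical agent that greedily follows
  the decoded prior shows the self-confirmatory post-error signature only
  if the neural signal itself integrates past actions.
* **neural decay rate** — per-unit maximum likelihood of an exponential
  action (or stimulus) kernel driving the pre-stimulus activity:
  ``Q_{t,n} = (1-α_n)Q_{t-1,n} + α_n·ζ_n^{a_{t-1}}`` with Poisson
  emission for spike counts, or ``… + α_n·ζ_n·a_{t-1}`` with Gaussian
  emission for imaging.  Session-level neural learning rates are then
  correlated with the behavioural learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.special import gammaln
from scipy.stats import ks_2samp, pearsonr

from .behavior_stats import _asymmetry_mask

ALPHA_BOUNDS = (1e-3, 1.0)


@dataclass
class OrthoResult:
    """Stepwise-orthogonalization weights and their pseudo null."""

    weights: np.ndarray                 # (K,)
    pseudo_weights: np.ndarray | None   # (M, K)
    flags: np.ndarray | None
    constant_lags: np.ndarray


@dataclass
class DecayFit:
    """Per-unit kernel decay fits and the session-level learning rate."""

    alpha: np.ndarray
    scale_pos: np.ndarray       # ζ⁺ (Poisson) or ζ (Gaussian)
    scale_neg: np.ndarray | None
    sigma: np.ndarray | None
    loglik: np.ndarray
    converged: np.ndarray
    modality: str

    @property
    def session_alpha(self) -> float:
        ok = self.converged
        return float(np.mean(self.alpha[ok])) if ok.any() else float("nan")


def orthogonalize_past(decoded_prior, events, K: int = 10) -> OrthoResult:
    """Stepwise regression of the decoded prior on past events.

    ``events`` are ±1-coded actions or stimulus sides.  Lag-1 is
    regressed first; each subsequent lag predicts the previous step's
    residual, which absorbs autocorrelation in the events.  Constant
    event columns at some lag get weight 0 and are flagged.
    """
    y = np.asarray(decoded_prior, dtype=float).copy()
    x = np.asarray(events, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("events and decoded prior must align")
    if K >= n:
        raise ValueError("K must be smaller than the number of trials")
    t = np.arange(K, n)
    resid = y[t].copy()
    weights = np.zeros(K)
    const = np.zeros(K, dtype=bool)
    for k in range(1, K + 1):
        xk = x[t - k]
        if np.ptp(xk) < 1e-12:
            const[k - 1] = True
            continue
        xc = xk - xk.mean()
        w = float(xc @ (resid - resid.mean()) / (xc @ xc))
        weights[k - 1] = w
        resid = resid - resid.mean() - w * xc  # intercept + slope removed
    return OrthoResult(weights=weights, pseudo_weights=None, flags=None,
                       constant_lags=const)


def _pm1_actions(table: pd.DataFrame) -> np.ndarray:
    ch = table["choice"].to_numpy()
    return np.where(ch == "right", 1.0, np.where(ch == "left", -1.0, 0.0))


def _pm1_stimuli(table: pd.DataFrame) -> np.ndarray:
    return np.where(table["stim_side"].to_numpy() == "right", 1.0, -1.0)


def orthogonalization_null(
    session: pd.DataFrame,
    X,
    decoded_prior,
    K: int = 10,
    M: int = 200,
    seed: int = 0,
    spec=None,
    events: str = "actions",
) -> OrthoResult:
    """Pseudo-weights for one session's stepwise regression.

    For ``events="actions"`` the action-kernel model is fitted to the
    session's behaviour and simulated on each pseudosession to obtain
    pseudoactions; for ``events="stimuli"`` the raw pseudosession stimuli
    are used directly (no behavioural model needed).  In both cases the
    pseudo Bayes-optimal prior is decoded from the *real* activity.
    """
    from .agents import simulate_agent
    from .behavior_fit import fit_model_map
    from .decoding import DecodeSpec, bayes_prior_target, nested_cv_decode
    from .taskgen import generate_pseudosessions

    spec = spec or DecodeSpec()
    ev = _pm1_actions(session) if events == "actions" else _pm1_stimuli(session)
    actual = orthogonalize_past(decoded_prior, ev, K)

    params = None
    if events == "actions":
        params = fit_model_map([session], "action_kernel", seed=seed)
    pseudos = generate_pseudosessions(session, M, seed=seed)
    W = np.full((M, K), np.nan)
    for i, ps in enumerate(pseudos):
        y_i = bayes_prior_target(ps, pseudos.config)
        dec_i = nested_cv_decode(X, y_i, spec, seed=seed).predictions
        if events == "actions":
            sim, _ = simulate_agent(ps, params, seed=seed + 7919 * i)
            ev_i = _pm1_actions(sim)
        else:
            ev_i = _pm1_stimuli(ps)
        W[i] = orthogonalize_past(dec_i, ev_i, K).weights
    return OrthoResult(weights=actual.weights, pseudo_weights=W, flags=None,
                       constant_lags=actual.constant_lags)


def orthogonalization_flags(results: list[OrthoResult]) -> dict:
    """Across-session mean weights vs the 95th percentile of pseudo means."""
    W = np.stack([r.weights for r in results])
    P = np.stack([r.pseudo_weights for r in results])  # (S, M, K)
    mean_w = W.mean(axis=0)
    pseudo_means = P.mean(axis=0)  # (M, K)
    thresh = np.percentile(pseudo_means, 95, axis=0)
    return {
        "mean_weights": mean_w,
        "pseudo_mean_weights": pseudo_means,
        "flags": mean_w > thresh,
    }


def neural_agent_asymmetry(decoded_prior, trials: pd.DataFrame,
                           min_from_reversal: int = 10) -> dict:
    """Post-outcome asymmetry of the greedy decoded-prior agent.

    The agent chooses right iff the decoded prior exceeds 0.5 (ties go
    left).  The behavioural asymmetry filters apply, except the
    zero-contrast restriction: the agent only sees pre-stimulus activity,
    so all contrasts are usable.
    """
    d = np.asarray(decoded_prior, dtype=float)
    hyp = trials.copy()
    hyp["choice"] = np.where(d > 0.5, "right", "left")
    mask, correct = _asymmetry_mask(hyp, zero_contrast_only=False,
                                    min_from_reversal=min_from_reversal)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return {"p_after_correct": np.nan, "p_after_error": np.nan, "n": 0}
    prev_ok = correct[idx - 1]
    return {
        "p_after_correct": float(correct[idx][prev_ok].mean()) if prev_ok.any() else np.nan,
        "p_after_error": float(correct[idx][~prev_ok].mean()) if (~prev_ok).any() else np.nan,
        "n": int(idx.size),
    }


def decay_unit_mask(counts: np.ndarray, prior, ks_p: float = 0.05,
                    min_rate: float = 0.2) -> np.ndarray:
    """Unit inclusion for the spiking decay fit.

    Keep a unit iff its median pre-stimulus count is positive, its mean
    count is at least one spike every five trials, and its count
    distribution differs (two-sample KS, p < ``ks_p``) between trials
    with prior above vs below 0.5.
    """
    counts = np.asarray(counts)
    p = np.asarray(prior, dtype=float)
    hi, lo = p > 0.5, p < 0.5
    out = np.zeros(counts.shape[0], dtype=bool)
    if not (hi.any() and lo.any()):
        return out
    for u in range(counts.shape[0]):
        c = counts[u]
        if np.median(c) <= 0 or c.mean() < min_rate:
            continue
        ks = ks_2samp(c[hi], c[lo])
        out[u] = ks.pvalue < ks_p
    return out


def _kernel_latent(alpha: float, drive: np.ndarray, updated: np.ndarray,
                   q0: float) -> np.ndarray:
    """Q_t from the exponential update, skipping non-updated trials."""
    n = len(drive)
    Q = np.empty(n)
    if updated.all():
        filt, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], drive,
                          zi=[(1.0 - alpha) * q0])
        Q[0] = q0
        Q[1:] = filt[:-1]
        return Q
    q = q0
    for t in range(n):
        Q[t] = q
        if updated[t]:
            q = (1.0 - alpha) * q + alpha * drive[t]
    return Q


def _fit_one_unit(x: np.ndarray, actions: np.ndarray, modality: str,
                  n_restarts: int, rng: np.random.Generator):
    """Bounded multi-start ML fit of (α, scales[, σ]) for one unit."""
    updated = actions != 0
    f_pos = (actions == 1).sum() / max(updated.sum(), 1)

    if modality == "ephys_counts":
        bounds = [ALPHA_BOUNDS, (1e-6, 100.0), (1e-6, 100.0)]
        lgx = gammaln(x + 1.0)

        def nll(th):
            a, zp, zn = th
            drive = np.where(actions == 1, zp, zn)
            q0 = f_pos * zp + (1 - f_pos) * zn
            Q = np.clip(_kernel_latent(a, drive, updated, q0), 1e-10, None)
            return float(-(x * np.log(Q) - Q - lgx).sum())

        starts = [(0.2, max(x.mean() * 1.5, 0.1), max(x.mean() * 0.5, 0.05))]
    else:
        bounds = [ALPHA_BOUNDS, (-50.0, 50.0), (1e-4, 50.0)]

        def nll(th):
            a, z, s = th
            drive = z * actions
            q0 = z * (2 * f_pos - 1)
            Q = _kernel_latent(a, drive, updated, q0)
            return float(0.5 * np.sum(((x - Q) / s) ** 2) + len(x) * np.log(s))

        starts = [(0.2, (np.abs(x).mean() or 1.0), max(x.std(), 0.1))]

    for _ in range(n_restarts - 1):
        starts.append(tuple(rng.uniform(lo, hi) for lo, hi in bounds))
    best = None
    for x0 in starts:
        try:
            res = minimize(nll, np.asarray(x0), method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    return best


def fit_decay(activity: np.ndarray, actions, modality: str,
              n_restarts: int = 10, seed: int = 0) -> DecayFit:
    """Per-unit exponential-kernel decay fits; see module docstring.

    ``actions`` are ±1 coded with 0 marking missed trials (no update).
    ``Q_0`` starts at the stationary mean of the recursion under the
    empirical action frequencies.  Units whose optimizer fails on every
    restart are dropped (``converged = False``).
    """
    X = np.asarray(activity, dtype=float)
    a = np.asarray(actions, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n_units = X.shape[0]
    rng = np.random.default_rng(seed)
    alpha = np.full(n_units, np.nan)
    sp = np.full(n_units, np.nan)
    sn = np.full(n_units, np.nan) if modality == "ephys_counts" else None
    sg = np.full(n_units, np.nan) if modality == "wfi_dff" else None
    ll = np.full(n_units, np.nan)
    ok = np.zeros(n_units, dtype=bool)
    for u in range(n_units):
        best = _fit_one_unit(X[u], a, modality, n_restarts, rng)
        if best is None:
            continue
        ok[u] = True
        ll[u] = -best.fun
        alpha[u] = best.x[0]
        sp[u] = best.x[1]
        if modality == "ephys_counts":
            sn[u] = best.x[2]
        else:
            sg[u] = best.x[2]
    return DecayFit(alpha=alpha, scale_pos=sp, scale_neg=sn, sigma=sg,
                    loglik=ll, converged=ok, modality=modality)


def timescale_correlation(neural_alphas, behavioural_alphas) -> dict:
    """Pearson correlation of session-level neural vs behavioural α."""
    x = np.asarray(neural_alphas, dtype=float)
    y = np.asarray(behavioural_alphas, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return {"r": float("nan"), "p_value": float("nan"), "n": int(ok.sum())}
    r, p = pearsonr(x[ok], y[ok])
    return {"r": float(r), "p_value": float(p), "n": int(ok.sum())}
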