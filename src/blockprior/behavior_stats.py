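"""Descriptive behavioural analyses.

Block-conditioned psychometric curves, zero-contrast performance, reversal
curves with exponential recovery fits (and leave-one-mouse-out jackknife),
and the post-outcome asymmetry that separates self-confirmatory
action-integrating strategies from stimulus-integrating ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import wilcoxon

REVERSAL_LAGS = np.concatenate([np.arange(-5, 0), np.arange(1, 21)])
"""Fitted lags around a block reversal: the 5 pre- and 20 post-reversal
trials.  The boundary trial t = 0 is excluded — the first stimulus of the
new block has not been observed yet, so performance there reflects the old
block, not the recovery."""


@dataclass
class ReversalFit:
    """Exponential recovery of accuracy after a block reversal.

    ``p(correct at t) = (B + (A-B)·exp(-t/τ))·1[t≥0] + B·1[t<0]``.
    """

    A: float
    B: float
    tau: float
    loss: float
    lags: np.ndarray
    curve: np.ndarray
    n_per_lag: np.ndarray
    tau_identifiable: bool = True


def _reversal_model(t, A, B, tau):
    return np.where(t >= 0, B + (A - B) * np.exp(-t / tau), B)


def reversal_indices(block_p: np.ndarray, include_leadin_switch: bool = False) -> np.ndarray:
    """Trial indices at which a new biased block starts."""
    rev = np.flatnonzero(np.diff(block_p) != 0) + 1
    if not include_leadin_switch:
        rev = rev[block_p[rev - 1] != 0.5]
    return rev


def reversal_curve(
    trials: pd.DataFrame,
    lags: np.ndarray = REVERSAL_LAGS,
    zero_contrast_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(correct counts, trial counts) per lag, pooled over reversals.

    One session or a pooled multi-session table; reversals are detected
    per session.
    """
    num = np.zeros(len(lags))
    den = np.zeros(len(lags))
    for _, sess in trials.groupby("session_id", sort=False):
        bp = sess["block_p_right"].to_numpy(dtype=float)
        correct = (sess["choice"].to_numpy() == sess["stim_side"].to_numpy()).astype(float)
        zc = sess["signed_contrast"].to_numpy(dtype=float) == 0
        use = zc if zero_contrast_only else np.ones(len(sess), dtype=bool)
        n = len(sess)
        for r in reversal_indices(bp):
            t = r + lags
            ok = (t >= 0) & (t < n)
            tt = t[ok]
            sel = use[tt]
            num[ok] += np.where(sel, correct[tt], 0.0)
            den[ok] += sel
    return num, den


def fit_reversal(
    num: np.ndarray,
    den: np.ndarray,
    lags: np.ndarray = REVERSAL_LAGS,
    n_restarts: int = 10,
    seed: int = 0,
) -> ReversalFit:
    """Weighted least squares of the exponential recovery on lag means.

    Lag means are weighted by their trial counts.  Bounds: A, B ∈ [0, 1],
    τ ∈ (0.1, 50].  Ten random restarts around the canonical start
    (A = 0.4, B = 0.7, τ = 5).
    """
    mask = den > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 lags with data to fit the reversal curve")
    x = lags[mask].astype(float)
    y = num[mask] / den[mask]
    w = den[mask]
    rng = np.random.default_rng(seed)
    starts = [(0.4, 0.7, 5.0)]
    starts += [
        (rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0.5, 20))
        for _ in range(n_restarts - 1)
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _reversal_model, x, y, p0=p0,
                bounds=([0.0, 0.0, 0.1], [1.0, 1.0, 50.0]),
                sigma=1.0 / np.sqrt(w), maxfev=5000,
            )
        except RuntimeError:
            continue
        loss = float((((_reversal_model(x, *popt) - y) ** 2) * w).sum())
        if best is None or loss < best[0]:
            best = (loss, popt)
    if best is None:
        raise RuntimeError("reversal fit failed for all restarts")
    loss, (A, B, tau) = best
    # τ is unidentifiable when there is no post-reversal drop to recover from
    identifiable = abs(A - B) > 1e-3
    return ReversalFit(
        A=float(A), B=float(B), tau=float(tau), loss=loss,
        lags=lags, curve=np.where(mask, num / np.maximum(den, 1), np.nan),
        n_per_lag=den, tau_identifiable=identifiable,
    )


def jackknife_tau(
    trials: pd.DataFrame,
    lags: np.ndarray = REVERSAL_LAGS,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Leave-one-mouse-out τ replicates and their median.

    Each replicate pools the reversal curves of the held-in mice and
    refits; failed replicate fits are dropped with a warning flag (NaN in
    the replicate vector).
    """
    mice = trials["mouse_id"].unique()
    if len(mice) < 3:
        raise ValueError("jackknife needs at least 3 mice")
    per_mouse = {}
    for m in mice:
        per_mouse[m] = reversal_curve(trials[trials["mouse_id"] == m], lags)
    taus = np.full(len(mice), np.nan)
    for i, m in enumerate(mice):
        num = sum(per_mouse[o][0] for o in mice if o != m)
        den = sum(per_mouse[o][1] for o in mice if o != m)
        try:
            taus[i] = fit_reversal(num, den, lags, seed=seed).tau
        except (ValueError, RuntimeError):
            continue
    return float(np.nanmedian(taus)), taus


def jackknife_se(replicates) -> float:
    """Jackknife standard error: sqrt((n-1)/n · Σ (θ_i - θ̄)²)."""
    x = np.asarray(replicates, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        return float("nan")
    return float(np.sqrt((n - 1) / n * np.sum((x - x.mean()) ** 2)))


def psychometric_by_block(trials: pd.DataFrame) -> pd.DataFrame:
    """P(choose right) per signed contrast × block type, mouse-averaged.

    Per-mouse curves are computed first, then averaged across mice; cells
    with no trials stay missing rather than zero.  Columns: block,
    signed_contrast, p_right (across-mouse mean), sem, n_mice.
    """
    inc = trials[trials["included"] & (trials["choice"] != "none")]
    rows = []
    for (block, c), grp in inc.groupby(["block_p_right", "signed_contrast"]):
        per_mouse = grp.groupby("mouse_id").apply(
            lambda g: (g["choice"] == "right").mean(), include_groups=False
        )
        rows.append(
            {
                "block": block,
                "signed_contrast": c,
                "p_right": per_mouse.mean(),
                "sem": per_mouse.std(ddof=1) / np.sqrt(len(per_mouse))
                if len(per_mouse) > 1 else np.nan,
                "n_mice": len(per_mouse),
            }
        )
    return pd.DataFrame(rows)


def zero_contrast_block_shift(psychometric: pd.DataFrame) -> float:
    """Right-block minus left-block P(right) at zero contrast."""
    z = psychometric[psychometric["signed_contrast"] == 0]
    hi = z.loc[z["block"] > 0.5, "p_right"]
    lo = z.loc[z["block"] < 0.5, "p_right"]
    if hi.empty or lo.empty:
        return np.nan
    return float(hi.iloc[0] - lo.iloc[0])


def _asymmetry_mask(sess: pd.DataFrame, zero_contrast_only: bool = True,
                    min_from_reversal: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Selection mask for the post-outcome asymmetry filters.

    Keeps trials t with: zero contrast at t (optional); block-conformant
    stimuli at t, t-1, t-2; correct at t-2; and at least
    ``min_from_reversal`` trials since the last reversal.  Returns
    (mask, correct_prev) where correct_prev is correctness at t-1.
    """
    bp = sess["block_p_right"].to_numpy(dtype=float)
    sides = sess["stim_side"].to_numpy()
    correct = sess["choice"].to_numpy() == sides
    zc = sess["signed_contrast"].to_numpy(dtype=float) == 0
    favoured = np.where(bp > 0.5, "right", "left")
    conformant = (sides == favoured) & (bp != 0.5)
    n = len(sess)

    rev = reversal_indices(bp, include_leadin_switch=True)
    since_rev = np.full(n, np.inf)
    last = -np.inf
    for t in range(n):
        if t in set(rev.tolist()):
            last = t
        since_rev[t] = t - last

    mask = np.zeros(n, dtype=bool)
    for t in range(2, n):
        if zero_contrast_only and not zc[t]:
            continue
        if not (conformant[t] and conformant[t - 1] and conformant[t - 2]):
            continue
        if not correct[t - 2]:
            continue
        if since_rev[t] < min_from_reversal:
            continue
        mask[t] = True
    return mask, correct


def post_outcome_asymmetry(
    trials: pd.DataFrame,
    zero_contrast_only: bool = True,
) -> dict:
    """P(correct | previous correct) vs P(correct | previous error).

    Action-integrating (self-confirmatory) agents are worse after an
    error on a block-conformant trial; stimulus-integrating agents are
    not, because the reward reveals the true side either way.  Computed
    per session, then compared with a paired Wilcoxon signed-rank test.
    """
    after_correct, after_error = [], []
    for _, sess in trials.groupby("session_id", sort=False):
        mask, correct = _asymmetry_mask(sess, zero_contrast_only)
        idx = np.flatnonzero(mask)
        prev_ok = correct[idx - 1]
        if (prev_ok.sum() > 0) and ((~prev_ok).sum() > 0):
            after_correct.append(correct[idx][prev_ok].mean())
            after_error.append(correct[idx][~prev_ok].mean())
    if not after_correct:
        return {"p_after_correct": np.nan, "p_after_error": np.nan,
                "statistic": np.nan, "p_value": np.nan, "n_sessions": 0}
    ac, ae = np.asarray(after_correct), np.asarray(after_error)
    if np.allclose(ac, ae):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(ac, ae)
    return {
        "p_after_correct": float(ac.mean()),
        "p_after_error": float(ae.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "n_sessions": len(ac),
    }
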