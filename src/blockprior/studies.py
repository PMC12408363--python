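"""Cohort-level simulation studies of the ideal-observer benchmarks.

These functions reproduce, from the generative process alone, the
benchmark quantities a Bayes-optimal probability-matching observer sets
for the task: zero-contrast accuracy, the post-reversal recovery
timescale, the prior/contrast rank correlation and the zero-contrast
trial rate.  The default cohort matches the study conditions: 139 mice,
about three sessions each, sessions of 645 trials (a 90-trial unbiased
lead-in followed by ~555 biased trials).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .agents import bayes_optimal_prior
from .behavior_stats import jackknife_tau
from .taskgen import TaskConfig, generate_session

N_MICE = 139
SESSIONS_PER_MOUSE = 3
N_TRIALS = 645  # 90 unbiased + ~555 biased


def simulate_prior_matching_cohort(
    n_mice: int = N_MICE,
    sessions_per_mouse: int = SESSIONS_PER_MOUSE,
    n_trials: int = N_TRIALS,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort whose choices are sampled from the Bayes-optimal prior.

    Every trial's choice is Bernoulli(prior); only zero-contrast trials
    are analysed downstream, where this probability-matching read-out is
    the observer the task benchmarks against.
    """
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials)
    tables = []
    for m in range(n_mice):
        for s in range(sessions_per_mouse):
            tab = generate_session(cfg, seed=int(rng.integers(2**31)),
                                   session_id=f"m{m}s{s}", mouse_id=f"m{m}")
            prior = bayes_optimal_prior(tab["stim_side"].to_numpy(), cfg).values
            choice_right = rng.random(n_trials) < prior
            tab["choice"] = np.where(choice_right, "right", "left")
            tab["reward"] = (tab["choice"] == tab["stim_side"]).astype(int)
            tab["reaction_time"] = 0.5
            tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def zero_contrast_accuracy(trials: pd.DataFrame) -> float:
    """Mean per-mouse accuracy on zero-contrast trials, in percent."""
    zc = trials[trials["signed_contrast"] == 0]
    per_mouse = zc.groupby("mouse_id").apply(
        lambda g: (g["choice"] == g["stim_side"]).mean(), include_groups=False
    )
    return float(100.0 * per_mouse.mean())


def reversal_tau_jackknife(trials: pd.DataFrame, seed: int = 0) -> float:
    """Jackknife-median decay constant of the post-reversal recovery."""
    median, _ = jackknife_tau(trials, seed=seed)
    return float(median)


def prior_contrast_spearman(
    n_sessions: int = 200,
    n_trials: int = N_TRIALS,
    seed: int = 0,
) -> float:
    """Spearman ρ between the Bayes-optimal prior and the signed contrast.

    Pooled over the biased-block trials of freshly simulated sessions —
    the correlation that motivates disentangling prior from stimulus in
    post-stimulus decoding.
    """
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials)
    priors, contrasts = [], []
    for _ in range(n_sessions):
        tab = generate_session(cfg, seed=int(rng.integers(2**31)))
        p = bayes_optimal_prior(tab["stim_side"].to_numpy(), cfg).values
        biased = tab["block_p_right"].to_numpy() != 0.5
        priors.append(p[biased])
        contrasts.append(tab["signed_contrast"].to_numpy()[biased])
    rho = spearmanr(np.concatenate(priors), np.concatenate(contrasts)).statistic
    return float(rho)


def zero_contrast_fraction(
    n_sessions: int = 100,
    n_trials: int = N_TRIALS,
    seed: int = 0,
) -> float:
    """Pooled zero-contrast trial fraction under the default task, percent."""
    rng = np.random.default_rng(seed)
    cfg = TaskConfig(n_trials=n_trials)
    zero = total = 0
    for _ in range(n_sessions):
        tab = generate_session(cfg, seed=int(rng.integers(2**31)))
        zero += int((tab["signed_contrast"] == 0).sum())
        total += len(tab)
    return float(100.0 * zero / total)
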