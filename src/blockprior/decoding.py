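"""Cross-validated linear decoding with pseudosession significance.

The decoding engine regresses a per-trial target (usually the
Bayes-optimal prior) on trial-wise neural activity with L1 (spiking) or
L2 (imaging) regularization, choosing the regularization weight by nested
cross-validation: interleaved random outer folds hold out 20% of trials,
and an inner grid search on the remaining 80% picks the weight.  The
procedure repeats over ten seeded runs; the reported score is the median
pooled held-out R² and the reported prediction the across-run mean.

Because both the prior and the activity drift slowly over a session,
ordinary significance tests are invalid.  Significance instead comes from
pseudosessions: counterfactual task sequences resampled from the true
generative process.  Decoding the pseudo-targets from the *real* activity
yields a null distribution of scores that inherits every slow confound;
the p-value is the actual score's quantile in that null, and the effect
size is the corrected R² (actual minus null median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.metrics import r2_score

from .agents import bayes_optimal_prior
from .synth_neural import NeuralMatrix
from .taskgen import generate_pseudosessions, session_config

EPHYS_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
WFI_GRID = (1e-5, 1e-4, 1e-3, 1e-2)
DLC_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
EYE_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1e3, 1e4)
NEUROMETRIC_EPHYS_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)

MIN_UNITS = 5  # inclusion rule: at least five units/pixels per region


@dataclass(frozen=True)
class DecodeSpec:
    """Decoder configuration; defaults follow the spiking-data settings."""

    penalty: str = "L1"
    grid: tuple = EPHYS_GRID
    outer_folds: int = 5
    inner_folds: int = 5
    n_runs: int = 10
    window: str = "iti"
    target: str = "bayes_optimal"

    def __post_init__(self) -> None:
        if self.penalty not in ("L1", "L2"):
            raise ValueError("penalty must be 'L1' or 'L2'")
        if not self.grid:
            raise ValueError("regularization grid must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")

    @staticmethod
    def ephys(**kw) -> "DecodeSpec":
        return replace(DecodeSpec(), **kw)

    @staticmethod
    def wfi(**kw) -> "DecodeSpec":
        return replace(
            DecodeSpec(penalty="L2", grid=WFI_GRID, outer_folds=50), **kw
        )

    @staticmethod
    def covariates(**kw) -> "DecodeSpec":
        return replace(DecodeSpec(penalty="L1", grid=DLC_GRID), **kw)

    @staticmethod
    def fast(**kw) -> "DecodeSpec":
        """Desk-scale spec for calibration studies and smoke tests."""
        return replace(
            DecodeSpec(penalty="L2", grid=(1e-3,), outer_folds=3,
                       inner_folds=2, n_runs=1),
            **kw,
        )


@dataclass
class DecodeResult:
    """Held-out decoding output, optionally with a pseudosession null."""

    predictions: np.ndarray
    per_run_r2: np.ndarray
    r2: float
    weights: np.ndarray          # mean over folds and runs, per unit
    grid_edge_hits: int = 0
    null_r2: np.ndarray | None = None
    p_value: float | None = None
    corrected_r2: float | None = None


def _estimator(penalty: str, alpha: float):
    if penalty == "L1":
        return Lasso(alpha=alpha, max_iter=5000)
    return Ridge(alpha=alpha)


def _as_features(X) -> np.ndarray:
    """(units × trials) NeuralMatrix or array → (trials × features)."""
    if isinstance(X, NeuralMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("decoder input must be 2-D (units × trials)")
    return X.T


def _fold_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Interleaved random fold assignment."""
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = np.arange(n) % k
    return labels


def nested_cv_decode(X, y, spec: DecodeSpec, seed: int = 0) -> DecodeResult:
    """Nested cross-validated decoding; see the module docstring.

    ``X`` is units × trials (a NeuralMatrix slice or array); ``y`` the
    per-trial target.  R² is computed on the pooled held-out predictions
    of each run; the median across runs is reported along with the mean
    held-out prediction.
    """
    F = _as_features(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if F.shape[0] != n:
        raise ValueError("X trials and y length differ")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate target: fewer than 2 distinct values")

    grid = np.asarray(spec.grid, dtype=float)
    preds_runs = np.empty((spec.n_runs, n))
    r2_runs = np.empty(spec.n_runs)
    weight_acc = np.zeros(F.shape[1])
    n_weightfits = 0
    edge_hits = 0

    for run in range(spec.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, run)))
        outer = _fold_labels(n, spec.outer_folds, rng)
        preds = np.empty(n)
        for fold in range(spec.outer_folds):
            test = outer == fold
            train = ~test
            Ftr, ytr = F[train], y[train]
            if len(grid) == 1:
                best_alpha = grid[0]
            else:
                inner = _fold_labels(train.sum(), spec.inner_folds, rng)
                mse = np.zeros(len(grid))
                for ifold in range(spec.inner_folds):
                    val = inner == ifold
                    fit = ~val
                    for gi, a in enumerate(grid):
                        est = _estimator(spec.penalty, a)
                        est.fit(Ftr[fit], ytr[fit])
                        mse[gi] += np.mean((est.predict(Ftr[val]) - ytr[val]) ** 2)
                best_alpha = grid[int(np.argmin(mse))]
                if np.argmin(mse) in (0, len(grid) - 1):
                    edge_hits += 1
            est = _estimator(spec.penalty, best_alpha)
            est.fit(Ftr, ytr)
            preds[test] = est.predict(F[test])
            weight_acc += est.coef_
            n_weightfits += 1
        preds_runs[run] = preds
        r2_runs[run] = r2_score(y, preds)

    return DecodeResult(
        predictions=preds_runs.mean(axis=0),
        per_run_r2=r2_runs,
        r2=float(np.median(r2_runs)),
        weights=weight_acc / n_weightfits,
        grid_edge_hits=edge_hits,
    )


def bayes_prior_target(table: pd.DataFrame, config=None) -> np.ndarray:
    """Default target builder: the Bayes-optimal prior of a task table."""
    cfg = config if config is not None else session_config(table)
    return bayes_optimal_prior(table["stim_side"].to_numpy(), cfg).values


def log_odds_target(table: pd.DataFrame, config=None) -> np.ndarray:
    p = bayes_prior_target(table, config)
    return np.log(p / (1.0 - p))


def true_block_target(table: pd.DataFrame, config=None) -> np.ndarray:
    return table["block_p_right"].to_numpy(dtype=float)


def signed_contrast_target(table: pd.DataFrame, config=None) -> np.ndarray:
    return table["signed_contrast"].to_numpy(dtype=float)


def pseudosession_significance(
    X,
    session: pd.DataFrame,
    target_builder=bayes_prior_target,
    spec: DecodeSpec = DecodeSpec(),
    M: int = 1000,
    seed: int = 0,
    config=None,
    collect: str | None = None,
) -> DecodeResult:
    """Decode the real target and M pseudo-targets; attach the null.

    ``collect`` may be ``"weights"`` or ``"predictions"`` to additionally
    keep the per-pseudosession weights / held-out predictions (stored on
    the result as ``pseudo_weights`` / ``pseudo_predictions``).
    The p-value uses add-one smoothing, ``p = (1 + #{null ≥ actual}) /
    (M + 1)``, so it is never exactly zero.
    """
    actual = nested_cv_decode(X, target_builder(session, config), spec, seed=seed)
    pseudos = generate_pseudosessions(session, M, seed=seed, config=config)
    null = np.empty(M)
    extra = []
    for i, ps in enumerate(pseudos):
        try:
            y_i = target_builder(ps, pseudos.config)
        except Exception as err:
            raise RuntimeError(f"target builder failed on pseudosession {i}") from err
        res = nested_cv_decode(X, y_i, spec, seed=seed)
        null[i] = res.r2
        if collect == "weights":
            extra.append(res.weights)
        elif collect == "predictions":
            extra.append(res.predictions)
    p = (1.0 + np.sum(null >= actual.r2)) / (M + 1.0)
    out = DecodeResult(
        predictions=actual.predictions,
        per_run_r2=actual.per_run_r2,
        r2=actual.r2,
        weights=actual.weights,
        grid_edge_hits=actual.grid_edge_hits,
        null_r2=null,
        p_value=float(p),
        corrected_r2=float(actual.r2 - np.median(null)),
    )
    if collect == "weights":
        out.pseudo_weights = np.asarray(extra)
    elif collect == "predictions":
        out.pseudo_predictions = np.asarray(extra)
    out.pseudosessions = pseudos
    return out


def fisher_combine(p_values) -> float:
    """Fisher's method: X² = -2 Σ ln p, referred to χ² with 2N d.f."""
    p = np.asarray(p_values, dtype=float)
    if (p <= 0).any():
        warnings.warn("p-value of 0 clipped to machine floor")
        p = np.clip(p, np.finfo(float).tiny, None)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * len(p)))


def bh_select(p_values, fdr: float = 0.01) -> np.ndarray:
    """Benjamini–Hochberg step-up selection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    m = len(p)
    order = np.argsort(p)
    thresh = fdr * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        flags[order[: k + 1]] = True
    return flags


def weight_significance(weights, pseudo_weights, q: float = 97.5) -> np.ndarray:
    """Two-sided per-unit flags against the pseudoweight percentiles."""
    pseudo = np.asarray(pseudo_weights, dtype=float)
    if pseudo.shape[0] < 40:
        warnings.warn("fewer than 40 pseudoweight draws: percentiles unstable")
    hi = np.percentile(pseudo, q, axis=0)
    lo = np.percentile(pseudo, 100 - q, axis=0)
    w = np.asarray(weights, dtype=float)
    return (w > hi) | (w < lo)


def sessions_needed(
    per_session_p,
    reps: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Median Fisher-combined p over random session subsets of each size.

    For each subset size N, draws ``reps`` random N-subsets of the
    region's session p-values, combines each with Fisher's method and
    reports the median combined p — an estimate of how many recordings a
    region needs before its significance is recoverable.
    """
    p = np.asarray(per_session_p, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for N in range(1, len(p) + 1):
        if N == len(p):
            meds = fisher_combine(p)
        else:
            combined = [
                fisher_combine(rng.choice(p, size=N, replace=False))
                for _ in range(reps)
            ]
            meds = float(np.median(combined))
        rows.append({"n_sessions": N, "median_p": meds,
                     "significant": meds < threshold})
    return pd.DataFrame(rows)


def region_summary(
    per_session: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Aggregate session-level decodings into a region map.

    ``per_session`` columns: region, session_id, p_value, corrected_r2.
    Output: region, n_sessions, combined_p, mean_corrected_r2,
    significant (Fisher p < 0.05) and significant_bh (BH at ``fdr``).
    """
    rows = []
    for region, grp in per_session.groupby("region"):
        rows.append(
            {
                "region": region,
                "n_sessions": len(grp),
                "combined_p": fisher_combine(grp["p_value"].to_numpy()),
                "mean_corrected_r2": float(grp["corrected_r2"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["combined_p"] < 0.05
    out["significant_bh"] = bh_select(out["combined_p"].to_numpy(), fdr=fdr)
    return out


def residual_decode(
    prior,
    covariates: pd.DataFrame,
    X,
    cov_spec: DecodeSpec | None = None,
    neural_spec: DecodeSpec | None = None,
    seed: int = 0,
    feature_importance: bool = False,
) -> dict:
    """Embodiment control: covariate, residual and neural decodings.

    Decodes the prior from ITI-averaged behavioural covariates (L1), forms
    the cross-validated residual (prior minus covariate prediction), and
    decodes both the prior and the residual from the neural activity.  If
    the neural signal merely embodies the covariates, the residual should
    not be decodable.  With ``feature_importance`` the drop in covariate
    R² when each feature is left out is returned as its importance.
    """
    cov_spec = cov_spec or DecodeSpec.covariates()
    neural_spec = neural_spec or DecodeSpec()
    y = np.asarray(prior, dtype=float)
    C = covariates.to_numpy(dtype=float).T  # features × trials

    constant = np.all(np.ptp(C, axis=1) < 1e-12)
    if constant:
        cov_res = None
        residual = y.copy()
        cov_r2 = np.nan
    else:
        cov_res = nested_cv_decode(C, y, cov_spec, seed=seed)
        residual = y - cov_res.predictions
        cov_r2 = cov_res.r2

    neural_res = nested_cv_decode(X, y, neural_spec, seed=seed)
    residual_res = nested_cv_decode(X, residual, neural_spec, seed=seed)
    out = {
        "covariate_r2": cov_r2,
        "neural_r2": neural_res.r2,
        "residual_r2": residual_res.r2,
        "residual": residual,
        "covariate_result": cov_res,
        "neural_result": neural_res,
        "residual_result": residual_res,
    }
    if feature_importance and not constant:
        importances = {}
        for col in covariates.columns:
            rest = covariates.drop(columns=[col]).to_numpy(dtype=float).T
            r = nested_cv_decode(rest, y, cov_spec, seed=seed)
            importances[col] = float(cov_r2 - r.r2)
        out["feature_importance"] = importances
    return out


def decile_curve(decoded_prior, trials: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """P(choose right) per decile of the decoded prior, zero-contrast trials."""
    zc = trials["signed_contrast"].to_numpy(dtype=float) == 0
    resp = trials["choice"].to_numpy() != "none"
    sel = zc & resp & trials["included"].to_numpy(dtype=bool)
    d = np.asarray(decoded_prior, dtype=float)[sel]
    right = (trials["choice"].to_numpy()[sel] == "right").astype(float)
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    rows = [
        {
            "decile": b + 1,
            "decoded_prior": d[idx == b].mean() if (idx == b).any() else np.nan,
            "p_right": right[idx == b].mean() if (idx == b).any() else np.nan,
            "n": int((idx == b).sum()),
        }
        for b in range(n_bins)
    ]
    return pd.DataFrame(rows)


def _logistic_slope(decoded_prior, choices_right) -> float:
    lr = LogisticRegression(C=1.0)
    lr.fit(np.asarray(decoded_prior, dtype=float).reshape(-1, 1),
           np.asarray(choices_right, dtype=int))
    return float(lr.coef_[0, 0])


def prior_choice_coupling(
    sessions: list[dict],
    M: int = 200,
    seed: int = 0,
    spec: DecodeSpec | None = None,
) -> dict:
    """Decoded-prior → choice coupling with a synthetic-session null.

    Each entry of ``sessions`` carries ``trials`` (table with choices),
    ``X`` (activity) and ``decoded_prior`` (cross-validated).  Per
    session, a logistic regression of choice on the decoded prior gives a
    slope.  The null refits the action-kernel model to the session's
    behaviour, simulates its choices on pseudosessions, decodes the
    pseudo-priors from the *real* activity, and refits the slopes: the
    mean slope is significant if it exceeds the 95th percentile of the
    mean pseudo-slopes.
    """
    from .agents import simulate_agent
    from .behavior_fit import fit_model_map

    spec = spec or DecodeSpec()
    slopes, pseudo_slopes = [], np.zeros((M, 0))
    per_session_null = []
    pooled_prior, pooled_trials = [], []

    for j, sess in enumerate(sessions):
        trials, X, dec = sess["trials"], sess["X"], sess["decoded_prior"]
        pooled_prior.append(np.asarray(dec))
        pooled_trials.append(trials)
        right = (trials["choice"].to_numpy() == "right").astype(int)
        if len(np.unique(right)) < 2:
            per_session_null.append(None)
            continue
        slopes.append(_logistic_slope(dec, right))

        params = fit_model_map([trials], "action_kernel", seed=seed + j)
        pseudos = generate_pseudosessions(trials, M, seed=seed + j)
        null_j = np.empty(M)
        for i, ps in enumerate(pseudos):
            ps_y = bayes_prior_target(ps, pseudos.config)
            dec_i = nested_cv_decode(X, ps_y, spec, seed=seed).predictions
            sim, _ = simulate_agent(ps, params, seed=seed + 7919 * i)
            r = (sim["choice"].to_numpy() == "right").astype(int)
            null_j[i] = _logistic_slope(dec_i, r) if len(np.unique(r)) > 1 else 0.0
        per_session_null.append(null_j)

    valid_null = [n for n in per_session_null if n is not None]
    mean_slope = float(np.mean(slopes)) if slopes else np.nan
    if valid_null:
        null_means = np.mean(np.stack(valid_null), axis=0)
        signif = mean_slope > np.percentile(null_means, 95)
    else:
        null_means, signif = np.array([]), False
    curve = decile_curve(np.concatenate(pooled_prior), pd.concat(pooled_trials))
    return {
        "decile_curve": curve,
        "slopes": np.asarray(slopes),
        "mean_slope": mean_slope,
        "null_mean_slopes": null_means,
        "significant": bool(signif),
    }
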