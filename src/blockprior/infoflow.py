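"""Directed flow of prior information between regions.

Each region's activity in the pre-stimulus window is segmented into bins
(ten 50 ms bins for spiking data, nine frames for imaging) and the prior
is decoded per bin, giving one decoded-prior time series per region over
the concatenated (trial, bin) axis.  Directed interactions between two
regions' series are quantified with spectral Granger causality: a
bivariate vector autoregression is fitted (order chosen by information
criterion), the Geweke frequency decomposition assigns an amplitude to
every Fourier frequency, and the overall Granger score is the mean
amplitude across frequencies.

Significance again relies on pseudosessions: pseudo-priors decoded from
the *real* activity undergo the identical Granger pipeline, producing a
null that inherits any shared slow drive — the property that makes the
test calibrated even though both regions decode the same prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, RidgeCV
from statsmodels.tsa.stattools import adfuller

from .decoding import MIN_UNITS, fisher_combine
from .synth_neural import NeuralMatrix
from .taskgen import generate_pseudosessions


@dataclass
class GrangerResult:
    """Directed-pair Granger scores, p-values and significance flags."""

    scores: dict            # (src, dst) -> score
    p_values: dict          # (src, dst) -> p (when a null was computed)
    flags: dict             # (src, dst) -> bool
    regions: list
    null_scores: dict = field(default_factory=dict)


def binwise_prior_decode(
    X: NeuralMatrix,
    prior,
    cv: int = 5,
    estimator: str | None = None,
    seed: int = 0,
    min_units: int = MIN_UNITS,
) -> dict[str, np.ndarray]:
    """Decode the prior from each region and bin; region → (trials, bins).

    Uses internally cross-validated L1 (spiking) or L2 (imaging)
    regression per bin.  Regions with fewer than ``min_units`` units are
    skipped.
    """
    if X.values.ndim != 3:
        raise ValueError("binned decoding needs units × trials × bins input")
    y = np.asarray(prior, dtype=float)
    use_l1 = (estimator or ("lasso" if X.modality == "ephys_counts" else "ridge")) == "lasso"
    out = {}
    for region in pd.unique(X.regions):
        mask = X.regions == region
        if mask.sum() < min_units:
            continue
        vals = X.values[mask]  # units × trials × bins
        n_bins = vals.shape[2]
        dec = np.empty((vals.shape[1], n_bins))
        for b in range(n_bins):
            F = vals[:, :, b].T.astype(float)
            if use_l1:
                est = LassoCV(cv=cv, random_state=seed, alphas=30)
            else:
                est = RidgeCV(alphas=np.logspace(-5, 2, 20))
            est.fit(F, y)
            dec[:, b] = est.predict(F)
        out[str(region)] = dec
    return out


def _var_fit(data: np.ndarray, max_order: int):
    """Least-squares bivariate VAR with AIC order selection."""
    n, k = data.shape
    best = None
    for p in range(1, max_order + 1):
        Y = data[p:]
        Z = np.hstack([data[p - lag: n - lag] for lag in range(1, p + 1)])
        Z = np.hstack([np.ones((len(Y), 1)), Z])
        coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ coef
        sigma = resid.T @ resid / len(Y) + 1e-12 * np.eye(k)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        aic = logdet + 2.0 * p * k * k / len(Y)
        if best is None or aic < best[0]:
            A = coef[1:].T.reshape(k, p, k).transpose(1, 0, 2)  # (p, k, k)
            best = (aic, A, sigma)
    if best is None:
        raise RuntimeError("VAR fit failed at every order")
    return best[1], best[2]


def _geweke_spectrum(A: np.ndarray, sigma: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Geweke measure f_{x→y}(ω) for the variable ordering (x, y)."""
    p, k, _ = A.shape
    out = np.empty(len(freqs))
    eye = np.eye(k)
    for i, w in enumerate(freqs):
        ew = np.exp(-1j * w * np.arange(1, p + 1))
        Aw = eye - np.tensordot(ew, A, axes=(0, 0))
        H = np.linalg.inv(Aw)
        S = H @ sigma @ H.conj().T
        syy = S[1, 1].real
        partial = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
        denom = syy - partial * np.abs(H[1, 0]) ** 2
        out[i] = np.log(syy / denom) if denom > 0 and syy > 0 else 0.0
    return np.clip(out, 0.0, None)


def granger_pair(
    series_src: np.ndarray,
    series_dst: np.ndarray,
    max_order: int = 5,
    check_stationarity: bool = True,
    n_freqs: int | None = None,
) -> float:
    """Spectral Granger score src → dst (mean amplitude over frequencies).

    Series are z-scored; unit-root series are differenced before fitting
    (flagged by the caller via :func:`granger_scores`).
    """
    return granger_scores(series_src, series_dst, max_order,
                          check_stationarity, n_freqs)["forward"]


def granger_scores(
    series_src,
    series_dst,
    max_order: int = 5,
    check_stationarity: bool = True,
    n_freqs: int | None = None,
) -> dict:
    """Both directed Granger scores for a pair of series."""
    x = np.asarray(series_src, dtype=float).ravel()
    y = np.asarray(series_dst, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    differenced = False
    if check_stationarity:
        try:
            p_x = adfuller(x, maxlag=10, autolag="AIC")[1]
            p_y = adfuller(y, maxlag=10, autolag="AIC")[1]
            if max(p_x, p_y) > 0.05:
                x, y = np.diff(x), np.diff(y)
                differenced = True
        except Exception:
            pass
    if x.std() < 1e-10 or y.std() < 1e-10:
        # a constant series neither sends nor receives information
        return {"forward": 0.0, "reverse": 0.0, "differenced": differenced}
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    data = np.column_stack([x, y])
    A, sigma = _var_fit(data, max_order)
    n = len(x)
    n_freqs = n_freqs or min(n // 2, 256)
    freqs = np.pi * (np.arange(1, n_freqs + 1)) / n_freqs
    fwd = float(_geweke_spectrum(A, sigma, freqs).mean())
    # reverse direction: swap the variable ordering
    A_sw = A[:, ::-1, :][:, :, ::-1]
    sigma_sw = sigma[::-1, ::-1]
    rev = float(_geweke_spectrum(A_sw, sigma_sw, freqs).mean())
    return {"forward": fwd, "reverse": rev, "differenced": differenced}


def _all_pair_scores(series_by_region: dict[str, np.ndarray], **kw) -> dict:
    scores = {}
    regions = list(series_by_region)
    for a, b in permutations(regions, 2):
        if (b, a) in scores:  # computed together with (a, b)
            continue
        s = granger_scores(series_by_region[a].ravel(),
                           series_by_region[b].ravel(), **kw)
        scores[(a, b)] = s["forward"]
        scores[(b, a)] = s["reverse"]
    return scores


def granger_significance(
    X: NeuralMatrix,
    session: pd.DataFrame,
    prior,
    M: int = 1000,
    seed: int = 0,
    cv: int = 3,
    max_order: int = 5,
    min_units: int = MIN_UNITS,
) -> GrangerResult:
    """Granger scores for every directed region pair with pseudo nulls.

    The null decodes each pseudosession's prior per bin from the real
    activity and reruns the full Granger pipeline; a pair is flagged when
    its actual score exceeds the 95th percentile of its pseudo scores.
    """
    if M < 2:
        import warnings

        warnings.warn("M < 2 gives a degenerate pseudo null")
    dec = binwise_prior_decode(X, prior, cv=cv, seed=seed, min_units=min_units)
    scores = _all_pair_scores(dec, max_order=max_order)

    pseudos = generate_pseudosessions(session, M, seed=seed)
    null = {pair: np.empty(M) for pair in scores}
    from .decoding import bayes_prior_target

    for i, ps in enumerate(pseudos):
        y_i = bayes_prior_target(ps, pseudos.config)
        dec_i = binwise_prior_decode(X, y_i, cv=cv, seed=seed, min_units=min_units)
        s_i = _all_pair_scores(dec_i, max_order=max_order)
        for pair in null:
            null[pair][i] = s_i[pair]

    p_values, flags = {}, {}
    for pair, sc in scores.items():
        n = null[pair]
        p_values[pair] = float((1.0 + np.sum(n >= sc)) / (M + 1.0))
        flags[pair] = bool(sc > np.percentile(n, 95))
    return GrangerResult(scores=scores, p_values=p_values, flags=flags,
                         regions=list(dec), null_scores=null)


def loop_fraction(flags: dict, cycle_length: int = 3) -> float:
    """Fraction of significant directed pairs lying on a directed cycle.

    ``flags`` maps (src, dst) to a bool.  For the default length 3, an
    edge u→v participates in a loop iff some w closes v→w→u.  Fewer than
    3 distinct nodes → NaN.
    """
    nodes = sorted({n for pair in flags for n in pair})
    if len(nodes) < 3:
        return float("nan")
    idx = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for (u, v), f in flags.items():
        if f:
            adj[idx[u], idx[v]] = True
    edges = np.argwhere(adj)
    if len(edges) == 0:
        return 0.0
    # paths of length L-1 from v back to u
    reach = np.linalg.matrix_power(adj.astype(int), cycle_length - 1) > 0
    in_loop = [reach[v, u] for u, v in edges]
    return float(np.mean(in_loop))


def aggregate_granger(
    per_session: pd.DataFrame,
    coarse_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fisher-combine directed-pair p-values across sessions and levels.

    ``per_session`` columns: src, dst, session_id, p_value.  Returns the
    region-level table (one row per directed pair) and, when a coarse
    grouping is given, a second Fisher combination across the pairs that
    map to each coarse directed pair.
    """
    region_rows = []
    for (src, dst), grp in per_session.groupby(["src", "dst"]):
        region_rows.append(
            {
                "src": src, "dst": dst, "n_sessions": len(grp),
                "combined_p": fisher_combine(grp["p_value"].to_numpy()),
            }
        )
    region_level = pd.DataFrame(region_rows)
    if coarse_map is None:
        return region_level, None
    rl = region_level.assign(
        src_c=region_level["src"].map(coarse_map),
        dst_c=region_level["dst"].map(coarse_map),
    )
    rl = rl[rl["src_c"] != rl["dst_c"]]
    coarse_rows = []
    for (s, d), grp in rl.groupby(["src_c", "dst_c"]):
        coarse_rows.append(
            {
                "src": s, "dst": d, "n_pairs": len(grp),
                "combined_p": fisher_combine(grp["combined_p"].to_numpy()),
            }
        )
    return region_level, pd.DataFrame(coarse_rows)
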