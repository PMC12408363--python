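"""Synthetic neural and covariate data with the structure the analyses assume.

Generators produce the inputs every downstream analysis consumes:

* spike counts (Poisson) and ΔF/F pixel activity (Gaussian, optionally
  mixed through a low-rank spatial matrix) coupled to a per-trial latent
  prior, with configurable slow drift — the confound the pseudosession
  test exists to defeat;
* a second spike-count flavour that emits from the exact exponential
  action/stimulus-kernel latent ``Q_{t,n} = (1-α)Q_{t-1,n} + α·ζ_n^{a_{t-1}}``
  used by the decay-rate recovery analyses;
* embodiment covariates (7 video-derived features + 2 eye-position
  coordinates), each optionally coupled to the prior;
* multi-region trial × bin series with optional directed lag-1 coupling
  between regions, for the information-flow analyses.

All generators are deterministic under a fixed seed and expose their
ground-truth latents in ``NeuralMatrix.truth`` so recovery tests are
closed-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

COVARIATE_NAMES = [
    "paw_l", "paw_r", "nose_x", "wheel_speed", "lick_rate",
    "whisk_l", "whisk_r", "eye_x", "eye_y",
]

EPHYS_N_BINS = 10   # 50 ms bins across the -600..-100 ms pre-stimulus window
WFI_N_BINS = 9      # imaging frames before stimulus onset


@dataclass
class NeuralMatrix:
    """Units-or-pixels × trials activity (optionally × bins)."""

    values: np.ndarray
    modality: str  # "ephys_counts" | "wfi_dff"
    regions: np.ndarray
    bin_edges: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("ephys_counts", "wfi_dff"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "ephys_counts":
            v = self.values
            if not (np.issubdtype(v.dtype, np.integer) or np.all(v == np.round(v))):
                raise ValueError("ephys counts must be integers")
            if (v < 0).any():
                raise ValueError("ephys counts must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def region_slice(self, region: str) -> "NeuralMatrix":
        mask = self.regions == region
        return NeuralMatrix(self.values[mask], self.modality,
                            self.regions[mask], self.bin_edges, self.truth)


@dataclass(frozen=True)
class SynthNeuralConfig:
    """Knobs of the generators; see the module docstring."""

    n_units: int = 20
    gain: float = 1.0
    gain_spread: float = 0.5        # per-unit gains ~ gain · U(1±spread)
    baseline: float = 1.0
    drift_amplitude: float = 0.0    # random-walk step s.d. (per trial)
    drift_form: str = "random_walk"  # or "linear"
    noise_scale: float = 1.0        # Gaussian emission s.d. (WFI)
    spatial_rank: int | None = None  # low-rank pixel mixing (WFI)
    region: str = "REG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.drift_form not in ("random_walk", "linear"):
            raise ValueError("drift_form must be 'random_walk' or 'linear'")


def _unit_gains(cfg: SynthNeuralConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = 1.0 - cfg.gain_spread, 1.0 + cfg.gain_spread
    return cfg.gain * rng.uniform(lo, hi, size=cfg.n_units)


def _drift(cfg: SynthNeuralConfig, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.drift_amplitude == 0:
        return np.zeros((cfg.n_units, n_trials))
    if cfg.drift_form == "linear":
        slope = cfg.drift_amplitude * rng.standard_normal(cfg.n_units)
        return slope[:, None] * np.linspace(0, 1, n_trials)
    steps = cfg.drift_amplitude * rng.standard_normal((cfg.n_units, n_trials))
    return np.cumsum(steps, axis=1)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def gen_ephys_counts(
    session: pd.DataFrame,
    prior_trace,
    cfg: SynthNeuralConfig,
) -> NeuralMatrix:
    """Poisson spike counts with rate softplus(baseline + gain·prior + drift)."""
    rng = np.random.default_rng(cfg.seed)
    prior = np.asarray(prior_trace, dtype=float)
    n = len(session)
    if len(prior) != n:
        raise ValueError("prior trace length must match the session")
    gains = _unit_gains(cfg, rng)
    drift = _drift(cfg, n, rng)
    rate = _softplus(cfg.baseline + gains[:, None] * prior[None, :] + drift)
    counts = rng.poisson(rate)
    return NeuralMatrix(
        values=counts, modality="ephys_counts",
        regions=np.full(cfg.n_units, cfg.region),
        truth={"latent": prior, "gains": gains, "rate": rate, "drift": drift},
    )


def gen_ephys_kernel_counts(
    actions: np.ndarray,
    alpha,
    zeta_pos,
    zeta_neg,
    n_trials: int | None = None,
    seed: int = 0,
) -> NeuralMatrix:
    """Spike counts emitted from the exact kernel latent.

    ``Q_{t,n} = (1-α_n)·Q_{t-1,n} + α_n·ζ_n^{a_{t-1}}`` with
    ``X_{t,n} ~ Poisson(Q_{t,n})``; ``actions`` are ±1 coded (0 = missed,
    no update).  ``Q_0`` starts at the stationary mean under the empirical
    action frequencies.  Scalars broadcast across units.
    """
    a = np.asarray(actions)
    n = len(a) if n_trials is None else n_trials
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    zp = np.broadcast_to(np.atleast_1d(zeta_pos).astype(float), alpha.shape)
    zn = np.broadcast_to(np.atleast_1d(zeta_neg).astype(float), alpha.shape)
    n_units = len(alpha)
    rng = np.random.default_rng(seed)
    f_pos = (a == 1).sum() / max((a != 0).sum(), 1)
    Q = f_pos * zp + (1 - f_pos) * zn
    lat = np.empty((n_units, n))
    for t in range(n):
        lat[:, t] = Q
        if a[t] == 1:
            Q = (1 - alpha) * Q + alpha * zp
        elif a[t] == -1:
            Q = (1 - alpha) * Q + alpha * zn
    counts = rng.poisson(lat)
    return NeuralMatrix(
        values=counts, modality="ephys_counts",
        regions=np.full(n_units, "REG"),
        truth={"latent": lat, "alpha": alpha, "zeta_pos": zp, "zeta_neg": zn},
    )


def gen_wfi_dff(
    session: pd.DataFrame,
    prior_trace,
    cfg: SynthNeuralConfig,
) -> NeuralMatrix:
    """Gaussian ΔF/F pixels: baseline + gain·prior through low-rank mixing.

    With ``spatial_rank = r`` the per-pixel means are a rank-r mixture of
    r latent channels (the first carrying the prior), making pixels
    collinear as in real imaging; ``rank = None`` leaves pixels
    independent.
    """
    rng = np.random.default_rng(cfg.seed)
    prior = np.asarray(prior_trace, dtype=float)
    n = len(session)
    gains = _unit_gains(cfg, rng)
    drift = _drift(cfg, n, rng)
    if cfg.spatial_rank is not None:
        r = cfg.spatial_rank
        if r > cfg.n_units:
            raise ValueError("spatial_rank cannot exceed n_pixels")
        channels = rng.standard_normal((r, n)) * 0.1
        channels[0] = prior
        mixing = rng.standard_normal((cfg.n_units, r))
        mixing[:, 0] = gains
        mean = cfg.baseline + mixing @ channels + drift
    else:
        mean = cfg.baseline + gains[:, None] * prior[None, :] + drift
    dff = mean + cfg.noise_scale * rng.standard_normal(mean.shape)
    return NeuralMatrix(
        values=dff, modality="wfi_dff",
        regions=np.full(cfg.n_units, cfg.region),
        truth={"latent": prior, "gains": gains, "mean": mean},
    )


def gen_wfi_kernel_dff(
    actions: np.ndarray,
    alpha,
    zeta,
    sigma,
    seed: int = 0,
) -> NeuralMatrix:
    """ΔF/F from the Gaussian kernel latent Q_t = (1-α)Q_{t-1} + α·ζ·a_{t-1}."""
    a = np.asarray(actions)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    zeta = np.broadcast_to(np.atleast_1d(zeta).astype(float), alpha.shape)
    sigma = np.broadcast_to(np.atleast_1d(sigma).astype(float), alpha.shape)
    n_units, n = len(alpha), len(a)
    rng = np.random.default_rng(seed)
    f_pos = (a == 1).sum() / max((a != 0).sum(), 1)
    Q = zeta * (2 * f_pos - 1)
    lat = np.empty((n_units, n))
    for t in range(n):
        lat[:, t] = Q
        if a[t] != 0:
            Q = (1 - alpha) * Q + alpha * zeta * a[t]
    dff = lat + sigma[:, None] * rng.standard_normal(lat.shape)
    return NeuralMatrix(
        values=dff, modality="wfi_dff", regions=np.full(n_units, "REG"),
        truth={"latent": lat, "alpha": alpha, "zeta": zeta, "sigma": sigma},
    )


def gen_covariates(
    session: pd.DataFrame,
    prior_trace,
    coupling=0.0,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ITI-averaged embodiment features: 7 video-derived + 2 eye position.

    Each column is ``baseline + coupling·prior + noise``; ``coupling``
    may be a scalar (applied to all features) or a 9-vector.
    """
    rng = np.random.default_rng(seed)
    prior = np.asarray(prior_trace, dtype=float)
    n = len(session)
    coup = np.broadcast_to(np.atleast_1d(np.asarray(coupling, dtype=float)),
                           (len(COVARIATE_NAMES),)).copy() \
        if np.ndim(coupling) else np.full(len(COVARIATE_NAMES), float(coupling))
    if len(coup) != len(COVARIATE_NAMES):
        raise ValueError(f"coupling must be scalar or length {len(COVARIATE_NAMES)}")
    baselines = rng.normal(0.0, 1.0, size=len(COVARIATE_NAMES))
    data = {
        name: baselines[i] + coup[i] * prior
        + noise_scale * rng.standard_normal(n)
        for i, name in enumerate(COVARIATE_NAMES)
    }
    return pd.DataFrame(data, index=session.index)


def gen_region_bin_series(
    session: pd.DataFrame,
    prior_trace,
    regions: list[str],
    coupling: list[tuple[str, str, float]] | None = None,
    n_units: int = 15,
    n_bins: int = EPHYS_N_BINS,
    modality: str = "ephys_counts",
    prior_gain: float = 1.0,
    noise_scale: float = 0.5,
    baseline: float = 1.0,
    seed: int = 0,
) -> NeuralMatrix:
    """Multi-region trial × bin activity with optional directed coupling.

    Each region carries a latent series over the concatenated (trial, bin)
    axis: ``z_r = prior_gain·prior[t] + ε_r`` with white innovation
    ``ε_r``.  A coupling entry ``(A, B, strength)`` injects
    ``z_B += strength · z_A`` shifted by one bin (crossing trial
    boundaries), giving a lag-1 directed influence A→B.  Units emit
    Poisson(softplus(baseline + gain·z)) or Gaussian per modality.
    """
    if coupling:
        for src, dst, _ in coupling:
            if src == dst:
                raise ValueError(f"self-loop coupling {src}->{dst} not allowed")
    rng = np.random.default_rng(seed)
    prior = np.asarray(prior_trace, dtype=float)
    n_trials = len(session)
    total = n_trials * n_bins
    base_prior = np.repeat(prior - prior.mean(), n_bins)

    latents = {
        r: prior_gain * base_prior + noise_scale * rng.standard_normal(total)
        for r in regions
    }
    if coupling:
        for src, dst, strength in coupling:
            shifted = np.concatenate([[0.0], latents[src][:-1]])
            latents[dst] = latents[dst] + strength * shifted

    all_vals, all_regions, gains = [], [], {}
    for r in regions:
        g = rng.uniform(0.5, 1.5, size=n_units)
        gains[r] = g
        z = latents[r].reshape(n_trials, n_bins)
        mean = baseline + g[:, None, None] * z[None, :, :]
        if modality == "ephys_counts":
            vals = rng.poisson(_softplus(mean))
        else:
            vals = mean + 0.5 * rng.standard_normal(mean.shape)
        all_vals.append(vals)
        all_regions.append(np.full(n_units, r))
    edges = -0.6 + 0.05 * np.arange(n_bins + 1) if n_bins == EPHYS_N_BINS else \
        np.arange(n_bins + 1, dtype=float)
    return NeuralMatrix(
        values=np.concatenate(all_vals, axis=0),
        modality=modality,
        regions=np.concatenate(all_regions),
        bin_edges=edges,
        truth={"latents": latents, "gains": gains, "prior": prior},
    )


def write_neural(nm: NeuralMatrix, path) -> None:
    """HDF5 layout: /counts or /dff, /regions, /bins, /truth/*."""
    key = "counts" if nm.modality == "ephys_counts" else "dff"
    with h5py.File(path, "w") as f:
        f.create_dataset(key, data=nm.values)
        f.create_dataset("regions", data=np.asarray(nm.regions, dtype="S"))
        if nm.bin_edges is not None:
            f.create_dataset("bins", data=nm.bin_edges)
        grp = f.create_group("truth")
        for k, v in nm.truth.items():
            if isinstance(v, dict):
                sub = grp.create_group(k)
                for kk, vv in v.items():
                    sub.create_dataset(str(kk), data=np.asarray(vv))
            else:
                grp.create_dataset(k, data=np.asarray(v))


def read_neural(path) -> NeuralMatrix:
    with h5py.File(path, "r") as f:
        if "counts" in f:
            values, modality = f["counts"][()], "ephys_counts"
        elif "dff" in f:
            values, modality = f["dff"][()], "wfi_dff"
        else:
            raise ValueError("file has neither /counts nor /dff")
        regions = f["regions"][()].astype(str)
        bins = f["bins"][()] if "bins" in f else None
        truth = {}
        if "truth" in f:
            for k, v in f["truth"].items():
                truth[k] = {kk: vv[()] for kk, vv in v.items()} \
                    if isinstance(v, h5py.Group) else v[()]
    return NeuralMatrix(values=values, modality=modality, regions=regions,
                        bin_edges=bins, truth=truth)
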