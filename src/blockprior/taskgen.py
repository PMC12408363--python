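"""Generative model of the biased-block visual decision task.

The task presents a grating on the left or right of a screen.  The side is
drawn i.i.d. within *blocks*: an initial unbiased block of ``n_unbiased``
trials with P(right) = 0.5, followed by alternating biased blocks in which
the favoured side appears with probability ``gamma`` (default 0.8).  Biased
block lengths follow a truncated exponential distribution
``p(l) ∝ exp(-l / tau_block)`` restricted to ``[block_min, block_max]``
(defaults: scale 60, bounds 20–100 trials).  Contrast magnitudes are drawn
independently of side; zero-contrast trials (probability 1/9 by default)
carry no stimulus information, so reward on those trials depends only on
the hidden block.

Pseudosessions — fresh draws from the same generative process, matched in
length to a recorded session — provide the null distributions used by all
significance tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "session_id",
    "mouse_id",
    "trial",
    "block_p_right",
    "stim_side",
    "signed_contrast",
    "choice",
    "reward",
    "reaction_time",
    "included",
]

#: contrast magnitudes used by the task, in ascending order
CONTRAST_MAGNITUDES = (0.0, 0.0625, 0.125, 0.25, 1.0)

RT_MIN_S = 0.08
RT_MAX_S = 2.0
MIN_INCLUDED_TRIALS = 250


class ConfigError(ValueError):
    """Raised when a task or analysis configuration is inconsistent."""


class FormatError(ValueError):
    """Raised when an on-disk trial table does not match the interface."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the block/stimulus generative process.

    Parameters
    ----------
    gamma
        Probability that the stimulus is on the block's favoured side.
    tau_block
        Exponential scale (in trials) of the biased-block length law.
    block_min, block_max
        Truncation bounds of the block length, inclusive.
    n_unbiased
        Length of the initial P(right) = 0.5 lead-in block.
    p_zero_contrast
        Probability of a zero-contrast trial; the remaining mass is spread
        uniformly over the non-zero magnitudes.
    n_trials
        Session length in trials (lead-in included).
    """

    gamma: float = 0.8
    tau_block: float = 60.0
    block_min: int = 20
    block_max: int = 100
    n_unbiased: int = 90
    contrast_magnitudes: tuple[float, ...] = CONTRAST_MAGNITUDES
    p_zero_contrast: float = 1.0 / 9.0
    n_trials: int = 645
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.gamma < 1.0:
            raise ConfigError(f"gamma must be in (0.5, 1), got {self.gamma}")
        if self.block_min > self.block_max:
            raise ConfigError("block_min must be <= block_max")
        if self.block_min < 1:
            raise ConfigError("block_min must be >= 1")
        if not 0.0 <= self.p_zero_contrast <= 1.0:
            raise ConfigError("p_zero_contrast must be in [0, 1]")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.n_unbiased < 0:
            raise ConfigError("n_unbiased must be >= 0")
        if 0.0 not in self.contrast_magnitudes:
            raise ConfigError("contrast_magnitudes must include 0")
        if self.tau_block <= 0:
            raise ConfigError("tau_block must be positive")

    @property
    def contrast_probs(self) -> np.ndarray:
        """Probability of each magnitude in :attr:`contrast_magnitudes`."""
        mags = np.asarray(self.contrast_magnitudes, dtype=float)
        n_nonzero = int(np.count_nonzero(mags))
        probs = np.full(mags.shape, (1.0 - self.p_zero_contrast) / n_nonzero)
        probs[mags == 0.0] = self.p_zero_contrast
        return probs

    def block_length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and pmf of the truncated-exponential block length."""
        lengths = np.arange(self.block_min, self.block_max + 1)
        w = np.exp(-lengths / self.tau_block)
        return lengths, w / w.sum()


@dataclass
class PseudosessionSet:
    """M resampled task sequences matched to one recorded session."""

    tables: list[pd.DataFrame]
    config: TaskConfig
    seed: int

    @property
    def M(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)

    def __getitem__(self, i: int) -> pd.DataFrame:
        return self.tables[i]


def _sample_block_length(cfg: TaskConfig, rng: np.random.Generator) -> int:
    lengths, pmf = cfg.block_length_pmf()
    return int(rng.choice(lengths, p=pmf))


def generate_session(
    config: TaskConfig,
    seed: int | None = None,
    session_id: str = "synth",
    mouse_id: str = "mouse",
) -> pd.DataFrame:
    """Draw one session of blocks, stimulus sides and contrasts.

    Choices, rewards and reaction times are left unset (``choice`` =
    ``"none"``); agents fill them in.  The last biased block may be
    truncated by the session end.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    n = config.n_trials

    block_p = np.empty(n)
    n_lead = min(config.n_unbiased, n)
    block_p[:n_lead] = 0.5
    t = n_lead
    # first biased side is a fair coin; afterwards sides alternate
    p_right = config.gamma if rng.random() < 0.5 else 1.0 - config.gamma
    while t < n:
        length = _sample_block_length(config, rng)
        block_p[t : t + length] = p_right
        t += length
        p_right = 1.0 - p_right if p_right > 0.5 else config.gamma

    block_p = np.round(block_p, 12)  # 1 - 0.8 must compare equal to 0.2
    sides = np.where(rng.random(n) < block_p, "right", "left")
    mags = rng.choice(
        np.asarray(config.contrast_magnitudes), size=n, p=config.contrast_probs
    )
    signed = np.where(sides == "right", mags, -mags)

    return pd.DataFrame(
        {
            "session_id": session_id,
            "mouse_id": mouse_id,
            "trial": np.arange(1, n + 1),
            "block_p_right": block_p,
            "stim_side": sides,
            "signed_contrast": signed,
            "choice": "none",
            "reward": 0,
            "reaction_time": np.nan,
            "included": True,
        }
    )


def session_config(table: pd.DataFrame, base: TaskConfig | None = None) -> TaskConfig:
    """Recover a TaskConfig matched to ``table`` (length and lead-in)."""
    base = base if base is not None else TaskConfig()
    n_unbiased = int((table["block_p_right"] == 0.5).to_numpy()[: len(table)].argmin())
    if (table["block_p_right"] == 0.5).all():
        n_unbiased = len(table)
    return replace(base, n_trials=len(table), n_unbiased=n_unbiased)


def generate_pseudosessions(
    session: pd.DataFrame,
    M: int,
    seed: int,
    config: TaskConfig | None = None,
) -> PseudosessionSet:
    """Resample ``M`` task sequences matched to ``session``'s config.

    Each pseudosession is an independent draw of blocks, sides and
    contrasts with the session's length and lead-in; the recorded neural
    activity is by construction independent of them, which is what makes
    the pseudosession null immune to slow drift.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    cfg = config if config is not None else session_config(session)
    child_seeds = np.random.SeedSequence(seed).spawn(M)
    tables = [
        generate_session(cfg, seed=np.random.default_rng(s).integers(2**31),
                         session_id=f"pseudo{i}")
        for i, s in enumerate(child_seeds)
    ]
    return PseudosessionSet(tables=tables, config=cfg, seed=seed)


def apply_inclusion_filters(session: pd.DataFrame) -> pd.DataFrame:
    """Flag trials outside the reaction-time window or without a response.

    Trials with no choice or reaction time outside [80 ms, 2 s] are marked
    excluded.  The returned table carries ``session_valid = False`` in its
    ``attrs`` when fewer than 250 trials survive.
    """
    out = session.copy()
    rt = out["reaction_time"].to_numpy(dtype=float)
    responded = out["choice"].to_numpy() != "none"
    ok = responded & (rt >= RT_MIN_S) & (rt <= RT_MAX_S)
    out["included"] = ok
    out.attrs["session_valid"] = bool(ok.sum() >= MIN_INCLUDED_TRIALS)
    return out


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 comma-separated CSV."""
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the mandatory columns."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise FormatError(f"empty trial table: {path}") from err
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
    if len(table) == 0:
        raise FormatError(f"trial table has no rows: {path}")
    table["included"] = table["included"].astype(bool)
    return table
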