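"""Behavioural prior models and the within-trial decision rule.

Three families of subjective prior over "stimulus on the right":

* **Bayes-optimal** — exact forward filtering over the hidden block state
  (favoured side × block age), assuming full knowledge of the generative
  process: truncated-exponential block lengths, side bias ``gamma``, and
  the unbiased lead-in.  The prior for trial ``t`` conditions on stimulus
  sides ``1..t-1`` only.
* **action / stimulus kernel** — an exponentially decaying running average
  ``π_t = (1-α)·π_{t-1} + α·1[event_{t-1} = right]`` of past choices or
  past stimulus sides, with learning rate ``α``.
* **true block** — the experimenter's block probability itself (an oracle
  the animal cannot know; used as a decoding control).

Within a trial the agent combines its prior with a noisy contrast
observation ``ĉ ~ N(c, σ_c²)``.  The observer is assumed to know the
trial's contrast magnitude (magnitude carries no side information), so the
likelihood of ``ĉ`` is Normal at ``±|c|`` and zero-contrast trials are
purely prior-driven.  Choices follow probability matching on the posterior
(or an argmax/greedy policy), with independent left/right lapse rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taskgen import TaskConfig

MODEL_KINDS = ("bayes_optimal", "action_kernel", "stimulus_kernel", "true_block")

#: Gauss–Hermite nodes/weights for marginalizing the sensory noise
_GH_POINTS = 61
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(_GH_POINTS)
_GH_W = _GH_W / _GH_W.sum()


@dataclass(frozen=True)
class AgentParams:
    """Parameters of a behavioural agent.

    ``alpha`` is only meaningful for the kernel models; ``sigma_c`` is the
    s.d. of the perceived signed contrast; lapses are the probabilities of
    a stimulus-independent left/right response.
    """

    kind: str = "bayes_optimal"
    alpha: float | None = None
    sigma_c: float = 0.25
    lapse_left: float = 0.0
    lapse_right: float = 0.0
    policy: str = "probability_matching"
    pi_init: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind in ("action_kernel", "stimulus_kernel"):
            if self.alpha is None or not 0.0 < self.alpha <= 1.0:
                raise ValueError("kernel models need alpha in (0, 1]")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.lapse_left < 0 or self.lapse_right < 0:
            raise ValueError("lapse rates must be nonnegative")
        if self.lapse_left + self.lapse_right >= 1.0:
            raise ValueError("lapse_left + lapse_right must be < 1")
        if self.policy not in ("probability_matching", "greedy"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if not 0.0 < self.pi_init < 1.0:
            raise ValueError("pi_init must be in (0, 1)")


@dataclass
class PriorTrace:
    """Per-trial prior probability of 'stimulus right' under one model."""

    values: np.ndarray
    kind: str

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)


def _encode_sides(sides) -> np.ndarray:
    """Map side tokens to {0: left, 1: right, -1: missed/none}."""
    arr = np.asarray(sides)
    if arr.dtype.kind in "if":
        out = arr.astype(int)
        if not np.isin(out, (-1, 0, 1)).all():
            raise ValueError("numeric side codes must be in {-1, 0, 1}")
        return out
    mapping = {"left": 0, "right": 1, "none": -1}
    try:
        return np.asarray([mapping[s] for s in arr])
    except KeyError as err:
        raise ValueError(f"unknown side token {err.args[0]!r}") from err


def _hazard(config: TaskConfig) -> np.ndarray:
    """Discrete hazard h(a) = P(block length = a | length >= a)."""
    lengths, pmf = config.block_length_pmf()
    full = np.zeros(config.block_max + 1)
    full[lengths] = pmf
    survival = np.concatenate([np.cumsum(full[::-1])[::-1], [0.0]])
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(survival[:-1] > 0, full / survival[:-1], 1.0)
    h[config.block_max] = 1.0  # forced switch at the truncation bound
    return h  # indexed by age a in 1..block_max (index 0 unused)


def bayes_optimal_prior(stim_sides, config: TaskConfig) -> PriorTrace:
    """Exact forward filter over the hidden block state.

    The hidden state is (favoured side, block age).  At each biased trial
    the block ends with hazard ``h(a)`` derived from the truncated
    exponential, in which case the favoured side flips and the age resets
    to 1.  The emission is P(stimulus = favoured side) = ``gamma``.  The
    returned prior for trial ``t`` uses sides ``1..t-1`` only; lead-in
    trials return exactly 0.5.
    """
    sides = _encode_sides(stim_sides)
    n = len(sides)
    gamma = config.gamma
    n_lead = min(config.n_unbiased, n)
    out = np.full(n, 0.5)

    h = _hazard(config)[1:]  # h[a-1] for age a
    amax = config.block_max
    # belief[side, age-1]; side 0 = left favoured, 1 = right favoured
    belief = np.zeros((2, amax))
    belief[:, 0] = 0.5
    # emission probability of a *right* stimulus given favoured side
    p_right_given = np.array([1.0 - gamma, gamma])

    for t in range(n_lead, n):
        out[t] = belief.sum(axis=1) @ p_right_given
        s = sides[t]
        if s == 1:
            belief *= p_right_given[:, None]
        elif s == 0:
            belief *= (1.0 - p_right_given)[:, None]
        # missed stimuli (-1) cannot occur for sides, but leave belief as-is
        tot = belief.sum()
        if tot <= 0:
            raise FloatingPointError("degenerate belief in forward filter")
        belief /= tot
        stay = belief * (1.0 - h)
        switched = (belief * h).sum(axis=1)
        new = np.zeros_like(belief)
        new[:, 1:] = stay[:, :-1]
        new[0, 0] = switched[1]
        new[1, 0] = switched[0]
        belief = new

    return PriorTrace(values=out, kind="bayes_optimal")


def kernel_prior(events, alpha: float, pi_init: float = 0.5,
                 kind: str = "action_kernel") -> PriorTrace:
    """Exponentially decaying average of past events.

    ``π_t = (1-α)·π_{t-1} + α·1[event_{t-1} = right]``; missed events
    (``none`` / -1) leave the prior unchanged, mirroring the convention
    that the update is skipped on missed trials.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    ev = _encode_sides(events)
    n = len(ev)
    if n and (ev >= 0).all():
        # no skips: π is an IIR filter of the event indicator
        from scipy.signal import lfilter

        x = (ev == 1).astype(float)
        filtered, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x,
                              zi=[(1.0 - alpha) * pi_init])
        out = np.empty(n)
        out[0] = pi_init
        out[1:] = filtered[:-1]
        # keep strictly inside (0, 1); α = 1 would otherwise pin π at 0/1
        return PriorTrace(values=np.clip(out, 1e-9, 1 - 1e-9), kind=kind)
    out = np.empty(n)
    pi = pi_init
    for t in range(n):
        out[t] = pi
        if ev[t] >= 0:
            pi = (1.0 - alpha) * pi + alpha * (ev[t] == 1)
    return PriorTrace(values=np.clip(out, 1e-9, 1 - 1e-9), kind=kind)


def _posterior_q(pi, mag, c_hat, sigma_c):
    """Posterior P(right | ĉ) with likelihood Normal(ĉ; ±mag, σ²)."""
    logit_pi = np.log(pi) - np.log1p(-pi)
    z = np.clip(logit_pi + 2.0 * mag * c_hat / sigma_c**2, -700, 700)
    return 1.0 / (1.0 + np.exp(-z))


def trial_choice_prob(p_right_prior, signed_contrast, params: AgentParams) -> np.ndarray:
    """Probability of choosing right, marginal over sensory noise.

    The perceived contrast ``ĉ ~ N(c, σ_c²)`` is integrated out with
    61-point Gauss–Hermite quadrature.  Probability matching maps the
    posterior ``q`` to itself; the greedy policy to ``1[q > 0.5]``.
    Lapses mix in a stimulus-independent response:
    ``P(right) = lapse_right + (1 - lapse_left - lapse_right) · m(q)``.
    """
    scalar = np.ndim(p_right_prior) == 0 and np.ndim(signed_contrast) == 0
    pi = np.atleast_1d(np.asarray(p_right_prior, dtype=float))
    c = np.atleast_1d(np.asarray(signed_contrast, dtype=float))
    pi, c = np.broadcast_arrays(pi, c)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("prior must be strictly in (0, 1)")
    mag = np.abs(c)
    # quadrature over ĉ = c + σ·x, x ~ N(0, 1)
    c_hat = c[..., None] + params.sigma_c * _GH_X
    q = _posterior_q(pi[..., None], mag[..., None], c_hat, params.sigma_c)
    m = q if params.policy == "probability_matching" else (q > 0.5).astype(float)
    matched = m @ _GH_W
    out = params.lapse_right + (1.0 - params.lapse_left - params.lapse_right) * matched
    return float(out[0]) if scalar else out


def prior_trace_for(session: pd.DataFrame, params: AgentParams,
                    config: TaskConfig | None = None,
                    events: np.ndarray | None = None) -> PriorTrace:
    """Prior trace of ``params.kind`` given a session's observed history."""
    from .taskgen import session_config

    if params.kind == "bayes_optimal":
        cfg = config if config is not None else session_config(session)
        return bayes_optimal_prior(session["stim_side"].to_numpy(), cfg)
    if params.kind == "true_block":
        return PriorTrace(session["block_p_right"].to_numpy(dtype=float), "true_block")
    if params.kind == "stimulus_kernel":
        ev = session["stim_side"].to_numpy()
    else:  # action_kernel: condition on the recorded choices
        ev = session["choice"].to_numpy() if events is None else events
    return kernel_prior(ev, params.alpha, params.pi_init, kind=params.kind)


def simulate_agent(
    session: pd.DataFrame,
    params: AgentParams,
    seed: int,
    config: TaskConfig | None = None,
    rt_lognorm: tuple[float, float] = (-1.0, 0.5),
) -> tuple[pd.DataFrame, PriorTrace]:
    """Simulate an agent on a session's stimuli; returns (table, trace).

    Action-kernel agents are closed-loop: each sampled choice feeds the
    next trial's prior.  Rewards follow the task rule (correct side, with
    zero-contrast trials rewarded on the hidden drawn side).  Reaction
    times are drawn log-normal so downstream inclusion filters have work
    to do.
    """
    rng = np.random.default_rng(seed)
    out = session.copy()
    n = len(out)
    sides = _encode_sides(out["stim_side"].to_numpy())
    contrasts = out["signed_contrast"].to_numpy(dtype=float)

    if params.kind == "action_kernel":
        pi = params.pi_init
        trace = np.empty(n)
        choices = np.empty(n, dtype=int)
        u = rng.random(n)
        for t in range(n):
            trace[t] = pi
            p_r = trial_choice_prob(pi, contrasts[t], params)
            choices[t] = int(u[t] < p_r)
            pi = (1.0 - params.alpha) * pi + params.alpha * choices[t]
        prior = PriorTrace(trace, "action_kernel")
    else:
        prior = prior_trace_for(out, params, config=config)
        p_r = trial_choice_prob(prior.values, contrasts, params)
        choices = (rng.random(n) < p_r).astype(int)

    out["choice"] = np.where(choices == 1, "right", "left")
    out["reward"] = (choices == sides).astype(int)
    mu, sd = rt_lognorm
    out["reaction_time"] = rng.lognormal(mu, sd, size=n)
    return out, prior


def action_loglik(session: pd.DataFrame, params: AgentParams,
                  config: TaskConfig | None = None,
                  trace: PriorTrace | None = None) -> np.ndarray:
    """Per-trial log p(choice_t | history, θ) for included, responded trials.

    The prior trace is conditioned on the *recorded* history (the animal's
    own actions for the action kernel), so the likelihood factorizes over
    trials.  Returns an array aligned to the session with NaN on excluded
    or missed trials.
    """
    if trace is None:
        trace = prior_trace_for(session, params, config=config)
    contrasts = session["signed_contrast"].to_numpy(dtype=float)
    choices = _encode_sides(session["choice"].to_numpy())
    included = session["included"].to_numpy(dtype=bool) & (choices >= 0)

    p_r = trial_choice_prob(trace.values, contrasts, params)
    p_choice = np.where(choices == 1, p_r, 1.0 - p_r)
    with np.errstate(divide="ignore"):
        ll = np.where(included, np.log(np.clip(p_choice, 1e-300, None)), np.nan)
    bad = included & ~np.isfinite(ll)
    if bad.any():
        raise FloatingPointError(
            f"non-finite log-likelihood at trial index {int(np.flatnonzero(bad)[0])}"
        )
    return ll
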