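"""Behavioural prior models: filter exactness, kernels, decision rule."""

import itertools

import numpy as np
import pytest

from blockprior import TaskConfig, generate_session
from blockprior.agents import (
    AgentParams,
    action_loglik,
    bayes_optimal_prior,
    kernel_prior,
    simulate_agent,
    trial_choice_prob,
)


def enumeration_prior(sides, cfg: TaskConfig) -> np.ndarray:
    """Brute-force Bayes-optimal prior by summing over block partitions.

    Enumerates every way of segmenting the session into blocks (including
    a final block truncated by the session end) and both choices of the
    first block's favoured side; the prior for trial t marginalizes all
    future stimuli.  Exponential in session length — oracle only.
    """
    sides = np.asarray(sides)
    n = len(sides)
    lengths, pmf = cfg.block_length_pmf()

    def partitions(pos):
        rem = n - pos
        if rem == 0:
            yield []
            return
        for l, p in zip(lengths, pmf):
            if l < rem:
                for rest in partitions(pos + int(l)):
                    yield [(int(l), p)] + rest
            elif l == rem:
                yield [(int(l), p)]
        p_trunc = pmf[lengths > rem].sum()
        if p_trunc > 0:
            yield [(rem, p_trunc)]

    def seq_prob(s):
        total = 0.0
        for blocks in partitions(0):
            p_blocks = np.prod([p for _, p in blocks])
            for side0 in (0, 1):
                prob = 0.5 * p_blocks
                side, pos = side0, 0
                for l, _ in blocks:
                    for t in range(pos, pos + l):
                        g = cfg.gamma if side == 1 else 1 - cfg.gamma
                        prob *= g if s[t] == 1 else 1 - g
                    side, pos = 1 - side, pos + l
                total += prob
        return total

    out = np.empty(n)
    for t in range(n):
        num = den = 0.0
        for tail in itertools.product((0, 1), repeat=n - t):
            s = np.concatenate([sides[:t], tail])
            p = seq_prob(s)
            den += p
            if tail[0] == 1:
                num += p
        out[t] = num / den
    return out


class TestBayesOptimalPrior:
    def test_leadin_and_bounds(self, default_config):
        tab = generate_session(default_config, seed=0)
        trace = bayes_optimal_prior(tab["stim_side"].to_numpy(), default_config)
        p = trace.values
        assert (p[:90] == 0.5).all()
        assert (p[90:] >= 0.2 - 1e-12).all() and (p[90:] <= 0.8 + 1e-12).all()

    def test_matches_enumeration_oracle(self, toy_config):
        rng = np.random.default_rng(3)
        for _ in range(4):
            sides = rng.integers(0, 2, toy_config.n_trials)
            filt = bayes_optimal_prior(sides, toy_config).values
            oracle = enumeration_prior(sides, toy_config)
            np.testing.assert_allclose(filt, oracle, atol=1e-10)

    def test_no_lookahead(self, default_config):
        tab = generate_session(default_config, seed=1)
        sides = tab["stim_side"].to_numpy()
        full = bayes_optimal_prior(sides, default_config).values
        short_cfg = TaskConfig(n_trials=200)
        short = bayes_optimal_prior(sides[:200], short_cfg).values
        np.testing.assert_allclose(full[:200], short, atol=1e-12)

    def test_side_mirror_symmetry(self, default_config):
        tab = generate_session(default_config, seed=2)
        sides = tab["stim_side"].to_numpy()
        mirrored = np.where(sides == "right", "left", "right")
        p = bayes_optimal_prior(sides, default_config).values
        q = bayes_optimal_prior(mirrored, default_config).values
        np.testing.assert_allclose(p, 1.0 - q, atol=1e-12)

    def test_unknown_token(self, default_config):
        with pytest.raises(ValueError, match="up"):
            bayes_optimal_prior(["up"] * 100, default_config)


class TestKernelPrior:
    def test_printed_update(self):
        trace = kernel_prior(["right"], alpha=0.1, pi_init=0.5).values
        # next-step value: (1-0.1)*0.5 + 0.1*1
        nxt = kernel_prior(["right", "left"], alpha=0.1, pi_init=0.5).values
        assert trace[0] == 0.5
        assert nxt[1] == pytest.approx(0.55)

    def test_fixed_point_and_limits(self):
        run = kernel_prior(["right"] * 200, alpha=0.3).values
        assert run[-1] == pytest.approx(1.0, abs=1e-8)
        # alpha -> 1: repeat last event
        rep = kernel_prior(["left", "right", "left"], alpha=1.0).values
        assert rep[1] == pytest.approx(0.0, abs=1e-8)
        assert rep[2] == pytest.approx(1.0, abs=1e-8)
        # alpha -> 0: stays at pi_init
        stay = kernel_prior(["right"] * 50, alpha=1e-9, pi_init=0.4).values
        assert np.allclose(stay, 0.4, atol=1e-6)

    def test_skip_markers_freeze_prior(self):
        ev = ["right", "none", "none", "left"]
        trace = kernel_prior(ev, alpha=0.2, pi_init=0.5).values
        assert trace[1] == trace[2] == trace[3] == pytest.approx(0.6)

    def test_kback_weight_geometry(self):
        """Impulse response of the k-back event is α(1-α)^(k-1)."""
        alpha = 0.25
        base = ["left"] * 12
        ref = kernel_prior(base, alpha).values
        for k in range(1, 6):
            ev = list(base)
            ev[-1 - k + 1 - 1] = "right"  # event k trials before the last
            bumped = kernel_prior(ev, alpha).values
            # symbolic unroll: π_t = Σ_j α(1-α)^(j-1) x_{t-j} + decayed init
            assert bumped[-1] - ref[-1] == pytest.approx(
                alpha * (1 - alpha) ** (k - 1), abs=1e-12
            )

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            kernel_prior(["left"], alpha=0.0)


class TestTrialChoiceProb:
    def test_zero_contrast_equals_prior(self):
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3)
        for prior in (0.2, 0.5, 0.8):
            assert trial_choice_prob(prior, 0.0, params) == pytest.approx(prior)

    def test_strong_contrast_dominates(self):
        params = AgentParams(kind="bayes_optimal", sigma_c=0.01)
        assert trial_choice_prob(0.2, 1.0, params) == pytest.approx(1.0, abs=1e-6)
        assert trial_choice_prob(0.8, -1.0, params) == pytest.approx(0.0, abs=1e-6)

    def test_lapse_composition(self):
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3,
                             lapse_left=0.1, lapse_right=0.1)
        # 0.1 + (1 - 0.2) * 0.8 at zero contrast
        assert trial_choice_prob(0.8, 0.0, params) == pytest.approx(0.74)

    def test_quadrature_matches_monte_carlo(self):
        """Noise marginalization agrees with direct sampling of ĉ."""
        params = AgentParams(kind="bayes_optimal", sigma_c=0.4)
        rng = np.random.default_rng(0)
        for prior, c in [(0.7, 0.125), (0.3, -0.25), (0.6, 0.0625)]:
            c_hat = rng.normal(c, params.sigma_c, size=400_000)
            z = np.log(prior / (1 - prior)) + 2 * abs(c) * c_hat / params.sigma_c**2
            q = 1.0 / (1.0 + np.exp(-z))
            assert trial_choice_prob(prior, c, params) == pytest.approx(
                q.mean(), abs=2e-3
            )

    def test_greedy_policy(self):
        greedy = AgentParams(kind="bayes_optimal", sigma_c=0.2, policy="greedy")
        assert trial_choice_prob(0.9, 0.0, greedy) == pytest.approx(1.0)
        assert trial_choice_prob(0.1, 0.0, greedy) == pytest.approx(0.0)

    def test_inconsistent_lapses_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(lapse_left=0.6, lapse_right=0.5)


class TestSimulateAgent:
    def test_deterministic_under_seed(self, session_table):
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3)
        a, _ = simulate_agent(session_table, params, seed=5)
        b, _ = simulate_agent(session_table, params, seed=5)
        assert a["choice"].equals(b["choice"])

    def test_greedy_omniscient_block_agent(self):
        """Greedy true-block agent hits gamma on zero-contrast trials."""
        cfg = TaskConfig(n_trials=4000)
        params = AgentParams(kind="true_block", sigma_c=0.3, policy="greedy")
        correct, total = 0, 0
        for seed in range(5):
            tab = generate_session(cfg, seed=seed)
            sim, _ = simulate_agent(tab, params, seed=seed + 100)
            zc = (sim["signed_contrast"] == 0) & (sim["block_p_right"] != 0.5)
            correct += (sim.loc[zc, "choice"] == sim.loc[zc, "stim_side"]).sum()
            total += zc.sum()
        assert correct / total == pytest.approx(0.8, abs=0.02)

    def test_reward_rule(self, session_table):
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3)
        sim, _ = simulate_agent(session_table, params, seed=7)
        expected = (sim["choice"] == sim["stim_side"]).astype(int)
        assert (sim["reward"] == expected).all()

    def test_action_kernel_closed_loop(self, session_table):
        """The recorded trace must obey the kernel update on sampled choices."""
        params = AgentParams(kind="action_kernel", alpha=0.3, sigma_c=0.3)
        sim, trace = simulate_agent(session_table, params, seed=9)
        replay = kernel_prior(sim["choice"].to_numpy(), 0.3).values
        np.testing.assert_allclose(trace.values, replay, atol=1e-9)


class TestActionLoglik:
    def test_deterministic_greedy_gives_zero(self, session_table):
        params = AgentParams(kind="true_block", sigma_c=1e-3, policy="greedy")
        sim, _ = simulate_agent(session_table, params, seed=1)
        ll = action_loglik(sim, params)
        assert np.nansum(ll) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prior_zero_contrast(self):
        cfg = TaskConfig(n_trials=120, n_unbiased=120)
        tab = generate_session(cfg, seed=0)
        tab["signed_contrast"] = 0.0
        tab["choice"] = np.where(np.arange(120) % 2 == 0, "left", "right")
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3)
        ll = action_loglik(tab, params)
        np.testing.assert_allclose(ll, np.log(0.5), atol=1e-12)

    def test_matches_simulation_frequency(self, session_table):
        """log p(a_t) agrees with the empirical choice frequency at fixed history."""
        params = AgentParams(kind="bayes_optimal", sigma_c=0.3)
        sim, trace = simulate_agent(session_table, params, seed=3)
        t = 200
        p_model = trial_choice_prob(trace.values[t],
                                    sim["signed_contrast"].iloc[t], params)
        draws = [
            simulate_agent(session_table, params, seed=s)[0]["choice"].iloc[t]
            for s in range(600)
        ]
        freq = np.mean(np.asarray(draws) == "right")
        assert p_model == pytest.approx(freq, abs=0.06)
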