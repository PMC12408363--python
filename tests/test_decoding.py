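"""Decoding engine, pseudosession significance, aggregation, couplings."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from blockprior.decoding import (
    DecodeSpec,
    _fold_labels,
    bayes_prior_target,
    bh_select,
    decile_curve,
    fisher_combine,
    log_odds_target,
    nested_cv_decode,
    prior_choice_coupling,
    pseudosession_significance,
    region_summary,
    residual_decode,
    sessions_needed,
    weight_significance,
)
from blockprior.synth_neural import SynthNeuralConfig, gen_covariates, gen_ephys_counts
from blockprior.taskgen import TaskConfig, generate_session


@pytest.fixture(scope="module")
def prior(session_table):
    return bayes_prior_target(session_table)


class TestNestedCV:
    def test_realizable_target(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 300))
        w = rng.standard_normal(8)
        y = w @ X
        res = nested_cv_decode(X, y, DecodeSpec.fast(grid=(1e-8,)), seed=0)
        assert res.r2 > 0.99

    def test_permuted_target_has_no_signal(self, session_table, prior):
        rng = np.random.default_rng(1)
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=10, gain=3.0, seed=2))
        y = rng.permutation(prior)
        res = nested_cv_decode(nm, y, DecodeSpec.fast(), seed=0)
        assert res.r2 < 0.05

    def test_grid_collapse_equals_plain_cv_oracle(self):
        """Single-value grid reduces to ordinary cross-validation."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 200))
        y = rng.standard_normal(6) @ X + 0.1 * rng.standard_normal(200)
        alpha = 1e-2
        spec = DecodeSpec(penalty="L2", grid=(alpha,), outer_folds=4,
                          inner_folds=2, n_runs=1)
        res = nested_cv_decode(X, y, spec, seed=7)
        # oracle: replay the same interleaved folds with bare sklearn Ridge
        folds_rng = np.random.default_rng(np.random.SeedSequence((7, 0)))
        labels = _fold_labels(200, 4, folds_rng)
        preds = np.empty(200)
        for f in range(4):
            test = labels == f
            est = Ridge(alpha=alpha).fit(X.T[~test], y[~test])
            preds[test] = est.predict(X.T[test])
        np.testing.assert_allclose(res.predictions, preds, atol=1e-10)

    def test_degenerate_target_rejected(self):
        X = np.random.default_rng(0).standard_normal((4, 50))
        with pytest.raises(ValueError):
            nested_cv_decode(X, np.ones(50), DecodeSpec.fast(), seed=0)

    def test_unit_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((7, 150))
        y = rng.standard_normal(7) @ X
        spec = DecodeSpec.fast(grid=(1e-4,))
        a = nested_cv_decode(X, y, spec, seed=1)
        perm = rng.permutation(7)
        b = nested_cv_decode(X[perm], y, spec, seed=1)
        assert a.r2 == pytest.approx(b.r2, abs=1e-10)
        np.testing.assert_allclose(a.weights[perm], b.weights, atol=1e-8)

    def test_log_odds_target_better_on_logit_linear_data(self, session_table, prior):
        logit = np.log(prior / (1 - prior))
        rng = np.random.default_rng(4)
        X = np.outer(rng.uniform(0.5, 1.5, 10), logit)
        X = X + 0.05 * rng.standard_normal(X.shape)
        spec = DecodeSpec.fast(grid=(1e-6,))
        r2_logit = nested_cv_decode(X, log_odds_target(session_table), spec, seed=0).r2
        r2_p = nested_cv_decode(X, prior, spec, seed=0).r2
        assert r2_logit > r2_p


class TestPseudosessionSignificance:
    def test_coupled_session_is_significant(self, session_table, prior):
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=12, gain=4.0, seed=5))
        res = pseudosession_significance(nm, session_table, spec=DecodeSpec.fast(),
                                         M=40, seed=6)
        assert res.p_value == pytest.approx(1 / 41, abs=1e-9)
        assert res.corrected_r2 > 0.3
        # corrected score recomputable from the stored null
        assert res.corrected_r2 == pytest.approx(
            res.r2 - np.median(res.null_r2), abs=1e-12
        )

    def test_type_one_error_calibrated_under_drift(self):
        """Drift-only activity yields ~5% rejections at the 5% level."""
        n_rep, M, hits = 60, 99, 0
        spec = DecodeSpec.fast()
        for rep in range(n_rep):
            cfg = TaskConfig(n_trials=250)
            sess = generate_session(cfg, seed=1000 + rep)
            y = bayes_prior_target(sess)
            ncfg = SynthNeuralConfig(n_units=8, gain=0.0, gain_spread=0.0,
                                     drift_amplitude=0.15, seed=rep)
            nm = gen_ephys_counts(sess, y, ncfg)
            res = pseudosession_significance(nm, sess, spec=spec, M=M,
                                             seed=2000 + rep)
            hits += res.p_value <= 0.05
        # binomial(60, 0.05): reject if far outside
        assert hits <= 9

    def test_p_values_in_unit_interval(self, session_table, prior):
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=6, gain=0.0, seed=8))
        res = pseudosession_significance(nm, session_table, spec=DecodeSpec.fast(),
                                         M=19, seed=9)
        assert 0 < res.p_value <= 1


class TestFisherAndBH:
    def test_fisher_closed_forms(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        # chi2_4 survival at -2*2*ln(0.5) = 2.7726: e^{-x/2}(1 + x/2)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)
        assert fisher_combine([0.123]) == pytest.approx(0.123, abs=1e-12)

    def test_fisher_zero_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            p = fisher_combine([0.0, 0.5])
        assert 0 < p < 1e-6

    def test_bh_edge_cases(self):
        assert not bh_select(np.ones(10)).any()
        flags = bh_select(np.r_[1e-6, np.full(241, 0.8)])
        assert flags[0] and flags.sum() == 1
        assert bh_select(np.array([])).size == 0

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.random(25)
            got = bh_select(p, fdr=0.1)
            # brute force: largest k with p_(k) <= k/m * q selects the k smallest
            order = np.argsort(p)
            ks = [k for k in range(1, 26) if p[order[k - 1]] <= 0.1 * k / 25]
            expect = np.zeros(25, dtype=bool)
            if ks:
                expect[order[: max(ks)]] = True
            np.testing.assert_array_equal(got, expect)


class TestWeightSignificance:
    def test_coupled_unit_flagged_null_not(self, session_table, prior):
        ncfg = SynthNeuralConfig(n_units=6, gain=6.0, seed=11)
        nm = gen_ephys_counts(session_table, prior, ncfg)
        res = pseudosession_significance(nm, session_table, spec=DecodeSpec.fast(),
                                         M=60, seed=12, collect="weights")
        flags = weight_significance(res.weights, res.pseudo_weights)
        assert flags.mean() > 0.5  # strongly coupled units stand out

    def test_identical_weights_not_flagged(self):
        pseudo = np.tile(np.linspace(-1, 1, 9), (50, 1))
        flags = weight_significance(pseudo[0], pseudo)
        assert not flags.any()

    def test_small_m_warns(self):
        with pytest.warns(UserWarning):
            weight_significance(np.zeros(3), np.zeros((10, 3)))


class TestSessionsNeeded:
    def test_full_subset_equals_fisher(self):
        p = np.array([0.04, 0.2, 0.6])
        out = sessions_needed(p, reps=50, seed=0)
        assert out["median_p"].iloc[-1] == pytest.approx(fisher_combine(p))

    def test_single_session(self):
        out = sessions_needed([0.3], reps=10, seed=0)
        assert out["median_p"].iloc[0] == pytest.approx(0.3)

    def test_evidence_accumulates(self):
        out = sessions_needed(np.full(8, 0.01), reps=200, seed=1)
        med = out["median_p"].to_numpy()
        assert (np.diff(med) < 0).all()


class TestRegionSummary:
    def test_flags_reproducible_from_p(self):
        per = pd.DataFrame(
            {
                "region": ["A", "A", "B", "C"],
                "session_id": ["s1", "s2", "s3", "s4"],
                "p_value": [0.01, 0.02, 0.9, 0.5],
                "corrected_r2": [0.2, 0.3, 0.0, 0.01],
            }
        )
        out = region_summary(per, fdr=0.05)
        a = out[out["region"] == "A"].iloc[0]
        assert a["combined_p"] == pytest.approx(fisher_combine([0.01, 0.02]))
        assert a["significant"]
        assert not out[out["region"] == "B"]["significant"].iloc[0]


class TestResidualDecode:
    def test_embodiment_limits(self, session_table, prior):
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=12, gain=4.0, seed=13))
        spec = DecodeSpec.fast()
        # covariates that fully explain the prior -> residual carries nothing
        cov_full = gen_covariates(session_table, prior, coupling=5.0,
                                  noise_scale=0.01, seed=14)
        full = residual_decode(prior, cov_full, nm, cov_spec=spec,
                               neural_spec=spec, seed=0)
        assert full["covariate_r2"] > 0.95
        assert full["residual_r2"] < 0.3
        # pure-noise covariates -> residual equals the prior
        cov_noise = gen_covariates(session_table, prior, coupling=0.0, seed=15)
        noise = residual_decode(prior, cov_noise, nm, cov_spec=spec,
                                neural_spec=spec, seed=0)
        assert noise["residual_r2"] == pytest.approx(noise["neural_r2"], abs=0.1)

    def test_constant_covariates(self, session_table, prior):
        cov = pd.DataFrame(np.ones((len(session_table), 3)),
                           columns=list("abc"))
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=8, gain=3.0, seed=16))
        out = residual_decode(prior, cov, nm, neural_spec=DecodeSpec.fast(),
                              seed=0)
        assert np.isnan(out["covariate_r2"])
        np.testing.assert_allclose(out["residual"], prior)

    def test_feature_importance_concentrates(self, session_table, prior):
        coup = np.zeros(9)
        coup[7] = 4.0
        cov = gen_covariates(session_table, prior, coupling=coup,
                             noise_scale=0.3, seed=17)
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=6, gain=2.0, seed=18))
        out = residual_decode(prior, cov, nm, cov_spec=DecodeSpec.fast(),
                              neural_spec=DecodeSpec.fast(), seed=0,
                              feature_importance=True)
        imp = out["feature_importance"]
        assert max(imp, key=imp.get) == "eye_x"


class TestPriorChoiceCoupling:
    def test_decile_curve_tracks_probability_matching(self):
        rng = np.random.default_rng(19)
        tabs, priors = [], []
        for s in range(8):
            sess = generate_session(TaskConfig(n_trials=400), seed=500 + s,
                                    session_id=f"s{s}")
            p = bayes_prior_target(sess)
            sess = sess.copy()
            sess["choice"] = np.where(rng.random(len(sess)) < p, "right", "left")
            tabs.append(sess)
            priors.append(p)
        curve = decile_curve(np.concatenate(priors), pd.concat(tabs))
        ok = curve.dropna()
        assert np.corrcoef(ok["decoded_prior"], ok["p_right"])[0, 1] > 0.8
        # end deciles bracket the middle: the curve rises overall
        assert ok["p_right"].iloc[-1] - ok["p_right"].iloc[0] > 0.3

    def test_uncoupled_choices_not_significant(self, session_table, prior):
        rng = np.random.default_rng(20)
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=8, gain=3.0, seed=21))
        spec = DecodeSpec.fast()
        dec = nested_cv_decode(nm, prior, spec, seed=0).predictions
        tab = session_table.copy()
        tab["choice"] = np.where(rng.random(len(tab)) < 0.5, "right", "left")
        out = prior_choice_coupling(
            [{"trials": tab, "X": nm, "decoded_prior": dec}],
            M=30, seed=22, spec=spec,
        )
        assert not out["significant"]

    def test_coupled_cohort_significant_and_monotone(self, session_table, prior):
        rng = np.random.default_rng(23)
        nm = gen_ephys_counts(session_table, prior,
                              SynthNeuralConfig(n_units=10, gain=5.0, seed=24))
        spec = DecodeSpec.fast()
        dec = nested_cv_decode(nm, prior, spec, seed=0).predictions
        tab = session_table.copy()
        tab["choice"] = np.where(rng.random(len(tab)) < prior, "right", "left")
        out = prior_choice_coupling(
            [{"trials": tab, "X": nm, "decoded_prior": dec}],
            M=30, seed=25, spec=spec,
        )
        assert out["mean_slope"] > 0
        assert out["significant"]
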