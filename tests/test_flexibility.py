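"""Flexibility slopes, bias, QC, psychometric thresholds, group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tempoflex as tf
from tempoflex.flexibility import (
    age_analysis,
    annotate_delta,
    bh_fdr,
    bias_summary,
    brown_forsythe,
    fit_logistic,
    fit_threshold,
    flexibility_discrimination,
    flexibility_tapping,
    pooled_threshold,
    qc_participant,
    tukey_filter,
)


class TestAnnotateDelta:
    def test_toy_sequence(self):
        df = pd.DataFrame({"trial_index": [1, 2, 3],
                           "ioi_ms": [500.0, 300.0, 700.0]})
        ann = annotate_delta(df)
        assert np.isnan(ann["delta_ioi_ms"].iloc[0])
        assert ann["delta_ioi_ms"].iloc[1:].tolist() == [-200.0, 400.0]
        assert ann["delta_sign"].iloc[1:].tolist() == ["faster", "slower"]

    def test_linear_plan_deltas_are_4ms_within_halves(self, rng):
        plan = tf.exp1_session_plan("linear", rng)
        df = pd.DataFrame({
            "trial_index": [t.trial_index for t in plan.trials],
            "ioi_ms": [t.ioi_ms for t in plan.trials],
            "is_boundary_repeat": [t.is_boundary_repeat for t in plan.trials],
        })
        ann = annotate_delta(df)
        deltas = ann["delta_ioi_ms"].dropna().abs()
        # ±4 ms everywhere except the single ramp junction (±2 ms)
        assert (deltas == 4.0).sum() == len(deltas) - 1
        assert sorted(deltas.unique()) == [2.0, 4.0]

    def test_boundary_repeat_is_predecessor_across_blocks(self):
        df = pd.DataFrame({
            "trial_index": [1, 2, 3, 4, 5],
            "ioi_ms": [500.0, 520.0, 520.0, 540.0, 560.0],
            "is_boundary_repeat": [False, False, True, False, False],
        })
        ann = annotate_delta(df)
        # trial 4's delta is relative to the repeated IOI (520), then the
        # repeat itself is dropped
        assert 3 not in ann["trial_index"].values
        assert ann.loc[ann.trial_index == 4, "delta_ioi_ms"].iloc[0] == 20.0

    def test_unordered_input_rejected(self):
        df = pd.DataFrame({"trial_index": [2, 1], "ioi_ms": [1.0, 2.0]})
        with pytest.raises(ValueError):
            annotate_delta(df)


from _oracles import grid_search_logistic


class TestFitLogistic:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 16)
        p = 1 / (1 + np.exp(-(-1.0 + 0.4 * x)))
        y = (rng.random(16) < p).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        intercept, slope, converged = fit_logistic(x, y)
        oi, os_ = grid_search_logistic(x, y)
        assert converged
        assert slope == pytest.approx(os_, abs=1e-4)
        assert intercept == pytest.approx(oi, abs=1e-4)

    def test_flat_response_gives_near_zero_slope(self, rng):
        x = np.tile(np.arange(10.0), 20)
        y = rng.integers(0, 2, len(x))
        _, slope, _ = fit_logistic(x, y)
        assert abs(slope) < 0.1

    def test_constant_y_flagged(self):
        i, s, converged = fit_logistic([1.0, 2.0, 3.0], [1, 1, 1])
        assert not converged and s == 0.0 and i > 0

    def test_complete_separation_capped(self):
        x = np.arange(10.0)
        y = (x > 4.5).astype(int)
        _, slope, converged = fit_logistic(x, y)
        assert not converged
        assert np.isfinite(slope) and slope > 0


class TestFlexibilityEstimates:
    def test_fully_adaptive_observer_has_near_zero_betas(self, rng):
        params = tf.ObserverParams(adapt_rate=1.0)
        betas = []
        for _ in range(8):
            dp, _ = tf.exp2_matched_design(rng)
            disc = annotate_delta(
                tf.simulate_discrimination_session(params, dp, rng))
            betas += [e.beta for e in flexibility_discrimination(disc)]
        assert abs(np.mean(betas)) < 0.0015

    def test_inflexible_observer_has_negative_betas(self, rng):
        params = tf.ObserverParams(adapt_rate=0.2)
        betas = {"faster": [], "slower": []}
        for _ in range(8):
            dp, _ = tf.exp2_matched_design(rng)
            disc = annotate_delta(
                tf.simulate_discrimination_session(params, dp, rng))
            for e in flexibility_discrimination(disc):
                betas[e.direction].append(e.beta)
        assert np.mean(betas["faster"]) < -0.001
        assert np.mean(betas["slower"]) < -0.001

    def test_level_means_monotone_in_adapt_rate(self, rng):
        means = []
        for ar in (0.2, 0.5, 0.9):
            params = tf.ObserverParams(adapt_rate=ar)
            b = []
            for _ in range(10):
                dp, _ = tf.exp2_matched_design(rng)
                disc = annotate_delta(
                    tf.simulate_discrimination_session(params, dp, rng))
                b += [e.beta for e in flexibility_discrimination(disc)
                      if e.direction == "faster"]
            means.append(np.mean(tukey_filter(np.array(b))))
        assert means[0] < means[1] < means[2]

    def test_tapping_sign_flip_contract(self):
        # |TME| rising with |dIOI| (positive raw slope) must yield negative
        # flexibility beta
        df = pd.DataFrame({
            "abs_delta": np.tile(np.arange(10.0, 110.0, 10.0), 3),
            "delta_sign": ["faster"] * 30,
            "tme": np.tile(np.arange(10.0, 110.0, 10.0), 3) * 1e-4,
        })
        est = flexibility_tapping(df)[0]
        assert est.beta == pytest.approx(-1e-4)

    def test_low_n_direction_flagged(self):
        df = pd.DataFrame({
            "abs_delta": [1.0, 2.0, 3.0, 4.0],
            "delta_sign": ["faster"] * 4,
            "accuracy": [1, 0, 1, 0],
        })
        est = flexibility_discrimination(df)[0]
        assert est.low_n


class TestBias:
    def test_hand_fixture_mean(self):
        df = pd.DataFrame({"delta_sign": ["faster"] * 4 + ["slower"] * 2,
                           "bias": [-1, 0, 0, -1, 1, 1]})
        b = bias_summary(df)
        assert b["faster"] == -0.5 and b["slower"] == 1.0

    def test_bias_accuracy_consistency(self, exp1_random_session):
        # |bias| is 1 exactly on errors, so mean|bias| = 1 - mean accuracy
        _, _, trials = exp1_random_session
        assert trials["bias"].abs().mean() == pytest.approx(
            1 - trials["accuracy"].mean())


class TestQc:
    def test_ceiling_flag_exp2_profile(self, rng):
        params = tf.ObserverParams(adapt_rate=1.0, base_noise=0.0, lapse=0.0)
        dp, _ = tf.exp2_matched_design(rng)
        disc = tf.simulate_discrimination_session(params, dp, rng)
        report = qc_participant(disc, profile="exp2")
        assert "ceiling" in report.flags
        assert "discrimination" in report.excluded_tasks

    def test_coin_flip_responder_flagged_at_chance(self, rng):
        dp, _ = tf.exp2_matched_design(rng)
        disc = tf.simulate_discrimination_session(tf.ObserverParams(), dp, rng)
        disc["accuracy"] = rng.integers(0, 2, len(disc))
        disc["dev"] = np.where(rng.random(len(disc)) < 0.5, -0.13, 0.13)
        report = qc_participant(disc, profile="exp2")
        assert "chance_both_directions" in report.flags

    def test_stimulus_ignoring_tapper_flagged(self):
        tap = pd.DataFrame({"ioi_ms": np.linspace(200, 1000, 81),
                            "median_iti": np.full(81, 600.0),
                            "n_itis": np.full(81, 10)})
        report = qc_participant(tap_trials=tap)
        assert "tap_slope_low" in report.flags
        assert "paced_tapping" in report.excluded_tasks

    def test_sparse_tapper_flagged(self):
        tap = pd.DataFrame({"ioi_ms": np.linspace(200, 1000, 81),
                            "median_iti": np.linspace(200, 1000, 81),
                            "n_itis": np.full(81, 5)})
        report = qc_participant(tap_trials=tap)
        assert "tap_count_low" in report.flags

    def test_flags_invariant_to_trial_order(self, rng):
        dp, _ = tf.exp2_matched_design(rng)
        disc = tf.simulate_discrimination_session(tf.ObserverParams(), dp, rng)
        r1 = qc_participant(disc, profile="exp2")
        r2 = qc_participant(disc.sample(frac=1, random_state=0),
                            profile="exp2")
        assert r1.flags == r2.flags


class TestPsychometricThreshold:
    def test_step_observer_threshold_at_step(self):
        devs = np.array([0.02, 0.05, 0.08, 0.10, 0.13, 0.16, 0.20])
        acc = np.where(devs >= 0.10, 1.0, 0.5)
        t = fit_threshold(devs, acc)
        assert t == pytest.approx(0.10, abs=0.02)

    def test_chance_everywhere_dropped(self):
        devs = np.array([0.02, 0.07, 0.11, 0.16, 0.20])
        assert fit_threshold(devs, np.full(5, 0.5)) is None

    def test_pooled_mean_filters_mad_outliers(self):
        thresholds = [0.10, 0.11, 0.12, 0.11, 0.95, None]
        assert pooled_threshold(thresholds) == pytest.approx(0.11, abs=0.005)

    def test_simulated_cohort_threshold_low_teens(self, rng):
        # the fixed ±13% deviation of the follow-up design sits near the
        # 75% threshold of this kind of observer
        thresholds = []
        for _ in range(6):
            plan = tf.exp1_session_plan("random", rng)
            trials = tf.simulate_discrimination_session(
                tf.ObserverParams(preferred_period_ms=rng.uniform(400, 800)),
                plan, rng)
            trials = trials[~trials.is_boundary_repeat]
            for sign in (-1, 1):
                sub = trials[np.sign(trials["dev"]) == sign]
                g = sub.groupby(sub["dev"].abs())["accuracy"].mean()
                thresholds.append(fit_threshold(g.index.to_numpy(),
                                                g.to_numpy()))
        pooled = pooled_threshold(thresholds)
        assert 0.05 < pooled < 0.2


class TestGroupStats:
    def test_bh_fdr_hand_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_fdr_single_p_unchanged(self):
        assert bh_fdr([0.037]).tolist() == [0.037]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 12))
    def test_bh_fdr_matches_statsmodels(self, seed, n):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).random(n)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
        assert np.all(ours >= p - 1e-12)  # adjustment never lowers a p-value

    def test_bh_fdr_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_brown_forsythe_identical_groups(self):
        F, p = brown_forsythe([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert F == 0.0 and p == 1.0

    def test_brown_forsythe_matches_scipy_levene_median(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(5, 3, 15)
        F, p = brown_forsythe(a, b)
        ref = stats.levene(a, b, center="median")
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_brown_forsythe_shift_invariant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 2, 10)
        F1, _ = brown_forsythe(a, b)
        F2, _ = brown_forsythe(a + 100, b)
        assert F1 == pytest.approx(F2)

    def test_tukey_filter_fences(self):
        x = np.array([5.0, 6, 7, 8, 9, 80.0])
        assert 80.0 not in tukey_filter(x)
        benign = np.array([4.0, 5, 6, 7, 8, 9])
        assert len(tukey_filter(benign)) == 6

    def test_tukey_filter_literal_mode(self):
        kept = tukey_filter(np.arange(1.0, 9.0), mode="literal")
        assert kept.tolist() == [3.0, 4.0, 5.0, 6.0]


class TestAgeAnalysis:
    def _table(self, rng, effect):
        n = 30
        age = rng.uniform(20, 76, n)
        signal = -effect * (age - age.mean()) / age.std()
        return pd.DataFrame({
            "age": age,
            "beta_disc_faster": signal + rng.normal(0, 1, n),
            "beta_disc_slower": signal + rng.normal(0, 1, n),
            "beta_tap_faster": signal + rng.normal(0, 1, n),
            "beta_tap_slower": signal + rng.normal(0, 1, n),
            "mean_accuracy": rng.normal(0.8, 0.05, n),
            "mean_abs_tme": rng.normal(0.05, 0.01, n),
        })

    def test_strong_decline_detected_after_fdr(self, rng):
        report = age_analysis(self._table(rng, effect=2.0))
        flex = report[report.family == "flexibility"]
        assert (flex["r"] < 0).all()
        assert (flex["p_adj"] < 0.05).all()

    def test_permuted_ages_break_correlation(self, rng):
        tbl = self._table(rng, effect=2.0)
        tbl["age"] = rng.permutation(tbl["age"].to_numpy())
        report = age_analysis(tbl)
        assert (report[report.family == "flexibility"]["p_adj"] > 0.05).all()

    def test_small_sample_refused(self, rng):
        tbl = self._table(rng, effect=1.0).head(4)
        with pytest.raises(ValueError):
            age_analysis(tbl)
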