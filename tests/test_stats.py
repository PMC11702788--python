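"""Hierarchical regressions: retention rules, recovery, contrasts, FDR."""

import numpy as np
import pandas as pd
import pytest

import aspursuit as asp
from aspursuit.errors import DesignCoverageError


def latent_records(preset, params, n_participants, seed, trials_scale=1.0, warmup=10):
    design = asp.make_design(preset, seed=seed, trials_scale=trials_scale)
    trials, _, truth = asp.simulate_experiment(
        design, params, n_participants=n_participants, seed=seed, with_traces=False
    )
    rec = asp.observed_records(trials, truth)
    return rec[rec["trial"] >= warmup].reset_index(drop=True)


class TestPrepareAnalysisTable:
    def _tables(self, n_trials=100):
        meta = pd.DataFrame(
            {
                "participant": 0,
                "block": "b1",
                "trial": np.arange(n_trials),
                "condition": ["HS" if i % 2 else "LS" for i in range(n_trials)],
                "is_reference": [bool(i % 2) for i in range(n_trials)],
                "P": 0.5,
            }
        )
        fits = meta[["participant", "block", "trial"]].copy()
        fits["aspv"] = 1.0
        return fits, meta

    def test_first_ten_trials_dropped(self):
        fits, meta = self._tables()
        out = asp.prepare_analysis_table(fits, meta)
        assert len(out) == 90
        assert out["trial"].min() == 10

    def test_control_mode_fifty(self):
        fits, meta = self._tables()
        assert len(asp.prepare_analysis_table(fits, meta, n_warmup=50)) == 50

    def test_first_trial_has_no_predecessor_class(self):
        fits, meta = self._tables()
        out = asp.prepare_analysis_table(fits, meta, n_warmup=0)
        assert out.loc[out["trial"] == 0, "prev_speed_class"].iloc[0] == "none"
        seq_ready = out[out["prev_speed_class"].isin(["high", "low"])]
        assert 0 not in seq_ready["trial"].values

    def test_orphan_fits_raise(self):
        fits, meta = self._tables()
        orphan = pd.DataFrame(
            {"participant": [9], "block": ["zz"], "trial": [0], "aspv": [1.0]}
        )
        with pytest.raises(ValueError, match="no metadata"):
            asp.prepare_analysis_table(pd.concat([fits, orphan]), meta)

    def test_qc_and_flagged_trials_dropped(self):
        fits, meta = self._tables()
        fits["flagged"] = False
        fits.loc[20, "flagged"] = True
        qc = meta[["participant", "block", "trial"]].copy()
        qc["excluded"] = qc["trial"] == 30
        out = asp.prepare_analysis_table(fits, meta, qc=qc)
        assert 20 not in out["trial"].values
        assert 30 not in out["trial"].values
        assert len(out) == 88


class TestProbabilityModel:
    def test_constant_response_zero_slope(self):
        rec = pd.DataFrame(
            {
                "participant": np.repeat([0, 1], 40),
                "P": np.tile(np.repeat([0.2, 0.8], 20), 2),
                "aSPv": 3.0,
            }
        )
        summary = asp.fit_probability_model(rec)
        assert summary.beta("P") == pytest.approx(0.0, abs=1e-8)

    def test_single_probability_level_rejected(self):
        rec = pd.DataFrame({"participant": [0, 1] * 10, "P": 0.5, "aSPv": 1.0})
        with pytest.raises(ValueError, match="probability levels"):
            asp.fit_probability_model(rec)

    def test_slope_recovered_from_matched_generative_model(self):
        params = asp.GenerativeParams(beta1=3.48, gamma_hist=0.0)
        rec = latent_records("exp1a", params, n_participants=10, seed=21, trials_scale=0.142)
        summary = asp.fit_probability_model(rec)
        lo, hi = summary.ci("P")
        assert lo <= 3.48 <= hi
        assert summary.p("P") < 1e-6

    def test_no_heterogeneity_shrinks_random_variances(self):
        params = asp.GenerativeParams(
            participant_sd_intercept=0.0, participant_sd_slope=0.0, gamma_hist=0.0
        )
        rec = latent_records("exp1a", params, n_participants=6, seed=2, trials_scale=0.1)
        summary = asp.fit_probability_model(rec)
        assert summary.random_variances.get("P", 0.0) < 0.05
        assert summary.random_variances.get("Group", 0.0) < 0.05

    def test_axis_interaction_enters_when_axis_present(self):
        params = asp.GenerativeParams(gamma_hist=0.0)
        rec = latent_records("exp1b", params, n_participants=4, seed=5, trials_scale=0.3)
        rec["aspv_x"] = rec["aSPv"] / np.sqrt(2)
        rec["aspv_y"] = rec["aSPv"] / np.sqrt(2)
        long = asp.to_long_axes(rec)
        summary = asp.fit_probability_model(long)
        assert any("axis" in name and ":" in name for name in summary.params.index)

    def test_single_participant_falls_back_to_ols(self):
        rec = pd.DataFrame(
            {
                "participant": 0,
                "P": np.tile([0.2, 0.8], 50),
                "aSPv": np.tile([1.0, 2.0], 50),
            }
        )
        with pytest.warns(UserWarning, match="single participant"):
            summary = asp.fit_probability_model(rec)
        assert summary.ladder_rung == "ols_single_participant"


class TestSequenceModel:
    def test_low_speed_predecessor_effect_recovered(self):
        params = asp.GenerativeParams(beta1=3.48, gamma_hist=0.5)
        rec = latent_records("exp1a", params, n_participants=10, seed=8, trials_scale=0.142)
        rec = rec[rec["prev_speed_class"].isin(["high", "low"])]
        summary = asp.fit_sequence_model(rec)
        est = summary.beta("TvN1[T.low]")
        lo, hi = summary.ci("TvN1[T.low]")
        assert est < 0 and hi < 0  # low predecessor lowers anticipation
        assert est == pytest.approx(-0.5, abs=0.25)

    def test_null_history_interaction_covered(self):
        params = asp.GenerativeParams(beta1=3.48, gamma_hist=0.0)
        rec = latent_records("exp1a", params, n_participants=10, seed=9, trials_scale=0.142)
        rec = rec[rec["prev_speed_class"].isin(["high", "low"])]
        summary = asp.fit_sequence_model(rec)
        lo, hi = summary.ci("P:TvN1[T.low]")
        assert lo <= 0.0 <= hi

    def test_rejects_none_class(self):
        rec = pd.DataFrame(
            {"participant": [0, 1], "P": [0.2, 0.8], "aSPv": [1.0, 2.0],
             "prev_speed_class": ["none", "high"]}
        )
        with pytest.raises(ValueError, match="high/low"):
            asp.fit_sequence_model(rec)


class TestHistoryProfile:
    def test_history_signs_follow_generative_effect(self):
        params = asp.GenerativeParams(beta1=0.0, gamma_hist=1.0, trial_sd=0.3)
        rec = latent_records("exp1a", params, n_participants=5, seed=4, trials_scale=0.142)
        prof = asp.history_profile(rec)
        mixtures = prof[(prof["P"] > 0) & (prof["P"] < 1)]
        assert (mixtures[mixtures["prev_speed_class"] == "high"]["delta_mean"] > 0).all()
        assert (mixtures[mixtures["prev_speed_class"] == "low"]["delta_mean"] < 0).all()

    def test_null_history_gives_flat_profile(self):
        params = asp.GenerativeParams(beta1=0.0, gamma_hist=0.0)
        rec = latent_records("exp1a", params, n_participants=8, seed=6, trials_scale=0.142)
        prof = asp.history_profile(rec)
        assert prof["delta_mean"].abs().max() < 0.2

    def test_pure_block_delta_is_exactly_zero(self):
        params = asp.GenerativeParams(gamma_hist=0.7)
        rec = latent_records("exp1a", params, n_participants=2, seed=7, trials_scale=0.1)
        prof = asp.history_profile(rec)
        row = prof[(prof["P"] == 1.0) & (prof["prev_speed_class"] == "high")]
        assert row["delta_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestKinematicsModel:
    def test_bayes_factor_identity(self):
        assert asp.bayes_factor_from_bic(100.0, 100.0) == pytest.approx(1.0)
        assert asp.bayes_factor_from_bic(110.0, 100.0) == pytest.approx(np.exp(5.0))

    def test_acceleration_effect_detected(self):
        params = asp.GenerativeParams(trial_sd=1.0, twi_end=0.2, speed_slope=0.2, beta0=1.0)
        rec = latent_records("exp3", params, n_participants=8, seed=3)
        out = asp.fit_kinematics_model(rec)
        assert out["bayes_factor"] > 100  # acceleration clearly needed
        # accel coefficient approximates speed_slope * twi_end / 2 = 0.02
        assert out["full"].beta("accel") == pytest.approx(0.02, abs=0.01)
        assert out["full"].beta("v0") == pytest.approx(0.2, abs=0.02)

    def test_missing_cell_raises(self):
        params = asp.GenerativeParams()
        rec = latent_records("exp3", params, n_participants=2, seed=1, trials_scale=0.2)
        with pytest.raises(DesignCoverageError, match="cells"):
            asp.fit_kinematics_model(rec[rec["condition"] != "v22a"])

    def test_ladder_preserves_fixed_design(self):
        params = asp.GenerativeParams(trial_sd=1.0)
        rec = latent_records("exp3", params, n_participants=4, seed=2, trials_scale=0.2)
        full = asp.stats.fit_mixed_ladder("aSPv ~ v0 * accel", rec, re_terms=["v0", "accel"])
        intercept_only = asp.stats.fit_mixed_ladder("aSPv ~ v0 * accel", rec, re_terms=[])
        assert list(full.params.index) == list(intercept_only.params.index)


class TestContrasts:
    def test_bh_boundary_all_rejected(self):
        adj = asp.benjamini_hochberg([0.01] * 36)
        assert np.allclose(adj, 0.01)
        assert (adj <= 0.05).all()

    def test_equal_means_control_false_discoveries(self):
        params = asp.GenerativeParams(speed_slope=0.0, twi_end=0.2, beta0=3.0)
        rec = latent_records("exp3", params, n_participants=6, seed=12, trials_scale=0.5)
        table = asp.pairwise_contrasts(rec)
        assert len(table) == 36
        assert (table["p_adj"] < 0.05).mean() <= 0.05

    def test_contrast_sign_tracks_condition_means(self):
        params = asp.GenerativeParams(speed_slope=0.2, twi_end=0.2, beta0=1.0)
        rec = latent_records("exp3", params, n_participants=6, seed=14, trials_scale=0.5)
        table = asp.pairwise_contrasts(rec)
        row = table[(table["cond_a"] == "v11a") & (table["cond_b"] == "v22d")]
        # v22d has the higher windowed mean speed, so v11a - v22d < 0
        assert row["estimate"].iloc[0] < 0
        assert row["p_adj"].iloc[0] < 0.001

    def test_fewer_than_two_levels_rejected(self):
        rec = pd.DataFrame({"participant": [0, 1], "condition": "v11c", "aSPv": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two condition"):
            asp.pairwise_contrasts(rec)


class TestConsistency:
    def test_slope_error_shrinks_with_sample_size(self):
        errors = []
        for scale, seed in [(0.05, 31), (0.2, 32), (0.8, 33)]:
            params = asp.GenerativeParams(
                beta1=3.48, gamma_hist=0.0,
                participant_sd_intercept=0.0, participant_sd_slope=0.0,
            )
            rec = latent_records("exp1a", params, n_participants=4, seed=seed, trials_scale=scale)
            summary = asp.fit_probability_model(rec)
            errors.append(abs(summary.beta("P") - 3.48))
        assert errors[2] < errors[0]
        assert errors[2] < 0.2
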