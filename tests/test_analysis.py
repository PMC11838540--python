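"""Filtering, standardization, the mixed model, and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from patchforage import (
    PolicyParams,
    compute_overstaying,
    earnings_by_duration_bins,
    earnings_by_travel_test,
    filter_visits,
    fit_residence_model,
    holm_bonferroni,
    policy_z_effects,
    posthoc_paired_tests,
    residence_visit_correlation,
    zscore,
)


def make_visits(rows, **defaults):
    base = {
        "session_id": "s", "subject_id": "r1", "travel_time": 5.0,
        "schedule": "standard", "side": "left", "visit_number": 1,
        "entry_time": 0.0, "exit_time": 1.0, "duration": 1.0,
        "pellets": 0, "complete": True,
    }
    base.update(defaults)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestFilterVisits:
    def test_two_sd_rule_excludes_outlier(self):
        """Ten 60-s visits plus one 400-s visit: the pooled mean is 90.9 s
        and SD 102.5 s, so only the 400-s visit exceeds the 2-SD band."""
        rows = [{"duration": 60.0} for _ in range(10)] + [{"duration": 400.0}]
        visits = make_visits(rows)
        retained, report = filter_visits(visits)
        assert report.n_outlier == 1
        assert len(retained) == 10
        assert (retained["duration"] == 60.0).all()
        assert report.duration_mean == pytest.approx(90.909, abs=1e-2)
        assert report.duration_sd == pytest.approx(102.5, abs=0.1)

    def test_incomplete_always_excluded(self):
        visits = make_visits(
            [{"duration": 60.0}, {"duration": 60.0, "complete": False}]
        )
        retained, report = filter_visits(visits)
        assert report.n_incomplete == 1
        assert len(retained) == 1

    def test_empty_table(self):
        retained, report = filter_visits(make_visits([{}]).iloc[0:0])
        assert len(retained) == 0
        assert report.n_input == 0

    def test_idempotent_with_fixed_statistics(self):
        rows = [{"duration": d} for d in [50, 55, 60, 65, 70, 300]]
        visits = make_visits(rows)
        first, report = filter_visits(visits)
        again, report2 = filter_visits(
            first, stats=(report.duration_mean, report.duration_sd)
        )
        pd.testing.assert_frame_equal(first, again)
        assert report2.n_outlier == 0

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            filter_visits(pd.DataFrame({"complete": [True]}))


class TestZscore:
    def test_hand_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1.0, 0.0, 1.0])

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            zscore([5, 5, 5])
        with pytest.raises(ValueError):
            zscore([1.0])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=40,
        ).filter(lambda xs: np.std(xs) > 1e-9)
    )
    def test_normalization_invariant(self, xs):
        z = zscore(xs)
        assert abs(z.mean()) < 1e-7
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-7)


class TestHolm:
    def test_hand_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_matches_reference_and_dominates_raw(self, ps):
        adj = holm_bonferroni(ps)
        ref = multipletests(ps, method="holm")[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()


def posthoc_fixture():
    """Three subjects, one visit-number cell each, all four conditions.

    Short travel: risky minus standard differences are [1, 2, 3], the
    textbook paired-t example (t = 2/(1/sqrt(3)) = 3.464, df = 2).  Long
    travel: risky equals standard exactly (t = 0, p = 1).
    """
    rows = []
    short_std = {"r1": 60.0, "r2": 60.0, "r3": 60.0}
    short_rsk = {"r1": 61.0, "r2": 62.0, "r3": 63.0}
    long_std = {"r1": 70.0, "r2": 71.5, "r3": 72.0}
    for subj in ("r1", "r2", "r3"):
        rows.append({"subject_id": subj, "travel_time": 5.0,
                     "schedule": "standard", "duration": short_std[subj]})
        rows.append({"subject_id": subj, "travel_time": 5.0,
                     "schedule": "risky", "duration": short_rsk[subj]})
        rows.append({"subject_id": subj, "travel_time": 30.0,
                     "schedule": "standard", "duration": long_std[subj]})
        rows.append({"subject_id": subj, "travel_time": 30.0,
                     "schedule": "risky", "duration": long_std[subj]})
    return make_visits(rows)


class TestPostHoc:
    def test_family_of_four_with_hand_computed_t(self):
        results = posthoc_paired_tests(posthoc_fixture())
        by_name = {r.comparison: r for r in results}
        assert len(results) == 4
        short = by_name["risky_vs_standard_short_travel"]
        assert short.t_statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-9)
        assert short.t_statistic == pytest.approx(3.464, abs=1e-3)
        assert short.df == 2
        long_ = by_name["risky_vs_standard_long_travel"]
        assert long_.t_statistic == 0.0
        assert long_.p_raw == 1.0
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-12
            assert r.p_adjusted <= 1.0
        family = holm_bonferroni([r.p_raw for r in results])
        np.testing.assert_allclose([r.p_adjusted for r in results], family)

    def test_missing_condition_is_named(self):
        visits = posthoc_fixture()
        with pytest.raises(ValueError, match="risky"):
            posthoc_paired_tests(visits[visits["schedule"] == "standard"])


class TestEarningsBins:
    def test_half_open_convention(self):
        rows = [
            {"duration": d, "pellets": i, "schedule": "standard"}
            for i, d in enumerate([0.0, 10.0, 20.0, 35.0, 40.0, 60.0])
        ]
        bins = earnings_by_duration_bins(make_visits(rows), n_bins=6)
        at35 = bins[(bins["bin_index"] == 3)]
        assert len(at35) == 1 and at35.iloc[0]["mean_pellets"] == 3
        # the last bin is closed: the 60-s visit lands in bin 5
        assert bins[bins["bin_index"] == 5].iloc[0]["mean_pellets"] == 5
        assert bins["flagged"].all()  # all bins hold a single visit here

    def test_single_visit_flagged(self):
        bins = earnings_by_duration_bins(
            make_visits([{"duration": 30.0, "pellets": 2}]), n_bins=6
        )
        populated = bins[bins["n"] > 0]
        assert len(populated) == 1
        assert populated.iloc[0]["flagged"]
        assert populated.iloc[0]["sd_pellets"] == 0.0

    def test_risky_variance_exceeds_standard(self, study_cohort):
        """On a simulated cohort the risky schedule matches standard mean
        earnings per duration bin but inflates the spread."""
        complete = study_cohort[study_cohort["complete"]]
        bins = earnings_by_duration_bins(complete, n_bins=6)
        wide = bins.pivot_table(
            index="bin_index", columns="schedule",
            values=["mean_pellets", "sd_pellets", "n"],
        )
        ok = wide[("n", "risky")].ge(30) & wide[("n", "standard")].ge(30)
        sd_r = wide.loc[ok, ("sd_pellets", "risky")]
        sd_s = wide.loc[ok, ("sd_pellets", "standard")]
        assert (sd_r > sd_s).all()
        mean_gap = (
            wide.loc[ok, ("mean_pellets", "risky")]
            - wide.loc[ok, ("mean_pellets", "standard")]
        ).abs()
        assert (mean_gap < 1.5).all()

    def test_empty_and_invalid(self):
        assert earnings_by_duration_bins(make_visits([{}]).iloc[0:0]).empty
        with pytest.raises(ValueError):
            earnings_by_duration_bins(make_visits([{"duration": 1.0}]), n_bins=0)


class TestOverstaying:
    def test_arithmetic_forced_by_definition(self):
        rows = [
            {"duration": 89.0, "travel_time": 5.0},
            {"duration": 120.0, "travel_time": 5.0},
            {"duration": 133.5, "travel_time": 5.0},
            {"duration": 147.0, "travel_time": 30.0},
        ]
        out = compute_overstaying(make_visits(rows))
        rec = out.records
        assert rec.loc[0, "overstay"] == 0.0
        assert rec.loc[1, "overstay"] == 31.0
        assert rec.loc[1, "normalized_duration"] == pytest.approx(1.348, abs=1e-3)
        assert rec.loc[2, "normalized_duration"] == pytest.approx(1.5)
        assert rec.loc[3, "overstay"] == 0.0  # long travel uses 147 s

    def test_positive_overstay_with_ci_excluding_zero(self, study_cohort):
        """Simulated cohorts under the default policy overstay in all four
        conditions with 95% confidence intervals excluding zero."""
        complete = study_cohort[study_cohort["complete"]]
        out = compute_overstaying(complete)
        assert len(out.condition_summary) == 4
        assert (out.condition_summary["mean_overstay"] > 0).all()
        assert (out.condition_summary["ci_low"] > 0).all()

    def test_by_patch_visit_table(self, study_cohort):
        out = compute_overstaying(study_cohort[study_cohort["complete"]])
        assert set(out.by_patch_visit["patch_visit"]) == {1, 2, 3, 4}
        assert (out.by_patch_visit["mean_normalized"] > 0).all()

    def test_invalid_optima_rejected(self):
        with pytest.raises(ValueError):
            compute_overstaying(make_visits([{"duration": 1.0}]), optimal_short=0.0)


class TestCorrelation:
    def test_hand_computed_r(self):
        rows = [
            {"visit_number": 1, "duration": 2.0},
            {"visit_number": 2, "duration": 1.0},
            {"visit_number": 3, "duration": 3.0},
        ]
        out = residence_visit_correlation(make_visits(rows))
        assert out.iloc[0]["r"] == pytest.approx(0.5)

    def test_perfect_correlation(self):
        rows = [{"visit_number": k, "duration": 10.0 + k} for k in range(1, 6)]
        out = residence_visit_correlation(make_visits(rows))
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_degenerate_input(self):
        rows = [{"visit_number": k, "duration": 5.0} for k in range(1, 6)]
        with pytest.raises(ValueError):
            residence_visit_correlation(make_visits(rows))

    def test_detects_within_session_trend_in_all_conditions(self):
        """A cohort generated with a steep within-session slope and no
        subject heterogeneity yields positive visit-number correlations
        in every travel/schedule condition."""
        from patchforage import generate_design, simulate_cohort

        policy = PolicyParams(visit_slope=4.0, subject_sd=0.0, residual_sd=20.0)
        designs = generate_design(4, 2, seed=61)
        visits = simulate_cohort(designs, policy, seed=62)
        out = residence_visit_correlation(visits[visits["complete"]])
        assert len(out) == 4
        assert (out["r"] > 0).all()


class TestEarningsByTravel:
    def test_pooled_variance_hand_example(self):
        """Session totals [1,2,3] (short) vs [4,5,6] (long): pooled-variance
        t = 3/sqrt(2/3) = 3.674 with df = 4, oriented long minus short."""
        rows = []
        for i, total in enumerate([1, 2, 3]):
            rows.append({"session_id": f"a{i}", "travel_time": 5.0,
                         "pellets": total})
        for i, total in enumerate([4, 5, 6]):
            rows.append({"session_id": f"b{i}", "travel_time": 30.0,
                         "pellets": total})
        res = earnings_by_travel_test(make_visits(rows))
        assert res.t_statistic == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4
        assert res.mean_difference == 3.0

    def test_identical_groups(self):
        rows = [
            {"session_id": f"s{i}{t}", "travel_time": t, "pellets": 5}
            for i in range(3)
            for t in (5.0, 30.0)
        ]
        res = earnings_by_travel_test(make_visits(rows))
        assert res.t_statistic == 0.0
        assert res.pvalue == 1.0

    def test_long_travel_deficit_on_cohort(self, study_cohort):
        res = earnings_by_travel_test(study_cohort)
        assert res.mean_difference < 0
        assert res.n_short + res.n_long == 64

    def test_small_group_rejected(self):
        rows = [
            {"session_id": "a", "travel_time": 5.0, "pellets": 3},
            {"session_id": "b", "travel_time": 30.0, "pellets": 4},
            {"session_id": "c", "travel_time": 30.0, "pellets": 5},
        ]
        with pytest.raises(ValueError):
            earnings_by_travel_test(make_visits(rows))


class TestResidenceModel:
    def test_term_set_matches_formula(self, study_cohort):
        retained, _ = filter_visits(study_cohort)
        fit = fit_residence_model(retained)
        assert set(fit.coefficients.index) == {
            "intercept", "travel_time", "reward_schedule",
            "visit_number", "schedule_x_travel",
        }
        non_intercept = fit.coefficients.drop(index="intercept")
        assert (non_intercept["se"] > 0).all()
        assert non_intercept["pvalue"].between(0, 1).all()
        assert fit.n_obs == len(retained)

    def test_recovers_generating_signs(self, study_cohort):
        complete = study_cohort[study_cohort["complete"]].reset_index(drop=True)
        fit = fit_residence_model(complete)
        assert fit.coefficients.loc["travel_time", "estimate"] > 0
        assert fit.coefficients.loc["reward_schedule", "estimate"] < 0
        assert fit.coefficients.loc["schedule_x_travel", "estimate"] > 0

    def test_single_subject_rejected(self, study_cohort):
        one = study_cohort[study_cohort["subject_id"] == "rat01"]
        with pytest.raises(ValueError, match="random intercept"):
            fit_residence_model(one)

    def test_missing_level_rejected(self, study_cohort):
        std_only = study_cohort[study_cohort["schedule"] == "standard"]
        with pytest.raises(ValueError, match="reward schedule"):
            fit_residence_model(std_only)

    def test_fuller_model_adds_side(self, small_cohort):
        retained, _ = filter_visits(small_cohort)
        fit = fit_residence_model(retained, include_side=True)
        assert any("side" in t for t in fit.coefficients.index)

    def test_z_effect_conversion_keys(self, study_cohort):
        eff = policy_z_effects(PolicyParams(), study_cohort)
        assert set(eff) == {
            "travel_time", "reward_schedule", "visit_number", "schedule_x_travel",
        }
        assert eff["schedule_x_travel"] > 0
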