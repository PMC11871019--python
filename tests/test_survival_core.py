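"""Cox machinery: partial likelihood, baseline hazard, residuals, KM curves."""

import numpy as np
import pytest

from survgwas import survival_core as sc

from conftest import grid_search_beta, naive_partial_loglik, random_small_cohort


def toy_cohort():
    """3 subjects: entry 0; exits 1,2,3; status 1,1,0; binary covariate 1,0,1."""
    return sc.Cohort(
        np.array(["a", "b", "c"]),
        np.zeros(3),
        np.array([1.0, 2.0, 3.0]),
        np.array([1, 1, 0]),
        np.zeros(3, int),
        np.array([1.0, 0.0, 1.0])[:, None],
    )


class TestFitCoxNull:
    def test_three_subject_toy_matches_grid_search(self):
        coh = toy_cohort()
        fit = sc.fit_cox_null(coh, include_sex=False)
        b_grid = grid_search_beta(coh.entry_age, coh.exit_age, coh.status,
                                  coh.covariates[:, 0])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(b_grid, abs=1e-4)

    def test_no_covariates_loglik_is_neg_log_risk_set_sizes(self):
        # 5 subjects, distinct exits, p=0: logPL = sum over events of -log(n at risk)
        entry = np.zeros(5)
        exit_ = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.array([1, 0, 1, 1, 0])
        coh = sc.Cohort(np.arange(5).astype(str), entry, exit_, status,
                        np.zeros(5, int), np.empty((5, 0)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        expected = -(np.log(5) + np.log(3) + np.log(2))
        assert fit.beta.size == 0
        assert fit.loglik == pytest.approx(expected, abs=1e-12)

    def test_replicating_every_subject_leaves_beta_unchanged(self):
        coh = toy_cohort()
        dbl = sc.Cohort(
            np.concatenate([coh.subject_id, coh.subject_id]),
            np.tile(coh.entry_age, 2), np.tile(coh.exit_age, 2),
            np.tile(coh.status, 2), np.tile(coh.sex, 2),
            np.tile(coh.covariates, (2, 1)),
        )
        b1 = sc.fit_cox_null(coh, include_sex=False).beta
        b2 = sc.fit_cox_null(dbl, include_sex=False).beta
        assert b2 == pytest.approx(b1, abs=1e-6)

    def test_loglik_matches_naive_double_loop_evaluation(self):
        rng = np.random.default_rng(9)
        entry, exit_, status, x = random_small_cohort(rng, 8)
        coh = sc.Cohort(np.arange(8).astype(str), entry, exit_, status,
                        np.zeros(8, int), x[:, None])
        fit = sc.fit_cox_null(coh, include_sex=False)
        naive = naive_partial_loglik(entry, exit_, status, fit.beta[0] * x)
        assert fit.loglik == pytest.approx(naive, abs=1e-10)

    def test_zero_events_raises(self):
        coh = sc.Cohort(np.array(["a", "b"]), np.zeros(2), np.ones(2),
                        np.zeros(2, int), np.zeros(2, int), np.empty((2, 0)))
        with pytest.raises(sc.CoxFitError, match="zero events"):
            sc.fit_cox_null(coh, include_sex=False)

    def test_collinear_covariates_raise(self):
        x = np.array([1.0, 0.0, 1.0])
        coh = sc.Cohort(np.array(list("abc")), np.zeros(3),
                        np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
                        np.zeros(3, int), np.column_stack([x, 2 * x]))
        with pytest.raises(sc.CoxFitError, match="rank deficient"):
            sc.fit_cox_null(coh, include_sex=False)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_small_random_cohorts_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        entry, exit_, status, x = random_small_cohort(rng, n)
        coh = sc.Cohort(np.arange(n).astype(str), entry, exit_, status,
                        np.zeros(n, int), x[:, None])
        fit = sc.fit_cox_null(coh, include_sex=False)
        if not fit.converged:  # monotone likelihood possible on tiny data
            return
        b_grid = grid_search_beta(entry, exit_, status, x)
        if abs(b_grid) > 9.5:  # grid boundary: effectively monotone
            return
        assert fit.beta[0] == pytest.approx(b_grid, abs=1e-4)


class TestBreslowBaseline:
    def test_single_subject_single_event_jumps_to_one(self):
        coh = sc.Cohort(np.array(["a"]), np.zeros(1), np.array([5.0]),
                        np.array([1]), np.zeros(1, int), np.empty((1, 0)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        assert fit.baseline_ages == pytest.approx([5.0])
        assert fit.baseline_cumhaz == pytest.approx([1.0])

    def test_matches_nelson_aalen_by_hand(self):
        # 4 subjects, no covariates, distinct events at 1,2,3; one censored at 4
        coh = sc.Cohort(np.arange(4).astype(str), np.zeros(4),
                        np.array([1.0, 2.0, 3.0, 4.0]),
                        np.array([1, 1, 1, 0]), np.zeros(4, int),
                        np.empty((4, 0)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        expected = np.cumsum([1 / 4, 1 / 3, 1 / 2])
        assert fit.baseline_cumhaz == pytest.approx(expected, abs=1e-12)

    def test_zero_coefficients_equal_no_covariate_baseline(self):
        rng = np.random.default_rng(7)
        n = 50
        coh = sc.Cohort(np.arange(n).astype(str), np.zeros(n),
                        rng.uniform(1, 10, n), rng.integers(0, 2, n),
                        np.zeros(n, int), rng.standard_normal((n, 2)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        fit.beta = np.zeros(2)
        ages1, ch1 = sc.breslow_cumhaz(coh, fit, include_sex=False)
        bare = sc.Cohort(coh.subject_id, coh.entry_age, coh.exit_age,
                         coh.status, coh.sex, np.empty((n, 0)))
        fit0 = sc.fit_cox_null(bare, include_sex=False)
        assert ch1 == pytest.approx(fit0.baseline_cumhaz, abs=1e-12)

    def test_nondecreasing_step_function(self, null_cohort):
        fit = sc.fit_cox_null(null_cohort)
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)
        assert np.all(fit.baseline_cumhaz >= 0)
        assert np.all(np.diff(fit.baseline_ages) > 0)


class TestMartingaleResiduals:
    def test_censored_before_first_event_has_zero_residual(self):
        coh = sc.Cohort(np.arange(3).astype(str), np.zeros(3),
                        np.array([1.0, 5.0, 6.0]), np.array([0, 1, 1]),
                        np.zeros(3, int), np.empty((3, 0)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        res = sc.martingale_residuals(coh, fit)
        assert res.residuals[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_residual_is_zero(self):
        coh = sc.Cohort(np.array(["a"]), np.zeros(1), np.array([5.0]),
                        np.array([1]), np.zeros(1, int), np.empty((1, 0)))
        fit = sc.fit_cox_null(coh, include_sex=False)
        res = sc.martingale_residuals(coh, fit)
        assert res.residuals[0] == pytest.approx(0.0, abs=1e-12)

    def test_toy_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        entry, exit_, status, x = random_small_cohort(rng, 5)
        coh = sc.Cohort(np.arange(5).astype(str), entry, exit_, status,
                        np.zeros(5, int), x[:, None])
        fit = sc.fit_cox_null(coh, include_sex=False)
        if not fit.converged:
            pytest.skip("monotone likelihood on this draw")
        b = grid_search_beta(entry, exit_, status, x)
        # oracle residuals: Breslow baseline at the grid-search beta
        eta = b * x
        event_ages = np.unique(exit_[status == 1])
        jumps = []
        for t in event_ages:
            at_risk = (entry < t) & (t <= exit_)
            d = np.sum((exit_ == t) & (status == 1))
            jumps.append(d / np.exp(eta[at_risk]).sum())
        cum = np.cumsum(jumps)

        def H0(t):
            idx = np.searchsorted(event_ages, t, side="right")
            return 0.0 if idx == 0 else cum[idx - 1]

        expected = np.array(
            [status[i] - (H0(exit_[i]) - H0(entry[i])) * np.exp(eta[i])
             for i in range(5)]
        )
        assert res_close(sc.martingale_residuals(coh, fit).residuals, expected)

    def test_sum_zero_and_bounded_by_status(self, null_cohort):
        fit = sc.fit_cox_null(null_cohort)
        res = sc.martingale_residuals(null_cohort, fit)
        n = len(null_cohort)
        assert abs(res.residuals.sum()) < 1e-6 * n
        assert np.all(res.residuals <= null_cohort.status + 1e-12)


def res_close(a, b, tol=2e-4):
    # grid-search beta is accurate to ~1e-4; residuals inherit that scale
    return np.max(np.abs(a - b)) < tol


class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        coh = sc.Cohort(np.arange(3).astype(str), np.zeros(3),
                        np.array([1.0, 2.0, 3.0]), np.zeros(3, int),
                        np.zeros(3, int), np.empty((3, 0)))
        curves = sc.kaplan_meier(coh, np.zeros(3, int))
        assert curves[0].ages.size == 0

    def test_hand_product_limit(self):
        # events at 60 and 70, censored at 65: S = 2/3 after 60, then 1/3... by hand
        coh = sc.Cohort(np.arange(3).astype(str), np.full(3, 50.0),
                        np.array([60.0, 65.0, 70.0]), np.array([1, 0, 1]),
                        np.zeros(3, int), np.empty((3, 0)))
        curve = sc.kaplan_meier(coh, np.zeros(3, int))[0]
        assert curve.ages == pytest.approx([60.0, 70.0])
        assert curve.survival == pytest.approx([2 / 3, 2 / 3 * (1 - 1 / 1)])
        assert list(curve.at_risk) == [3, 1]

    def test_delayed_entry_shrinks_early_risk_sets(self):
        # the late entrant is not at risk for the age-55 event
        coh = sc.Cohort(np.arange(3).astype(str),
                        np.array([50.0, 50.0, 60.0]),
                        np.array([55.0, 70.0, 75.0]),
                        np.array([1, 1, 1]), np.zeros(3, int), np.empty((3, 0)))
        curve = sc.kaplan_meier(coh, np.zeros(3, int))[0]
        assert list(curve.at_risk) == [2, 2, 1]

    def test_neg_log_survival_tracks_breslow_cumhaz(self, null_cohort):
        bare = sc.Cohort(null_cohort.subject_id, null_cohort.entry_age,
                         null_cohort.exit_age, null_cohort.status,
                         null_cohort.sex, np.empty((len(null_cohort), 0)))
        fit = sc.fit_cox_null(bare, include_sex=False)
        curve = sc.kaplan_meier(bare, np.zeros(len(bare), int))[0]
        mask = curve.at_risk > 30
        diff = np.abs(-np.log(curve.survival[mask]) - fit.baseline_cumhaz[mask])
        assert diff.max() < 5.0 / np.min(curve.at_risk[mask])

    def test_empty_group_errors(self):
        coh = toy_cohort()
        with pytest.raises(ValueError):
            sc.kaplan_meier(coh.subset(np.zeros(3, bool)), np.array([]))


class TestCarrierHazard:
    def test_permuted_carriers_center_on_null_hr(self, null_cohort):
        rng = np.random.default_rng(5)
        carrier = (rng.random(len(null_cohort)) < 0.05).astype(float)
        logs = []
        for _ in range(40):
            est = sc.cox_carrier_hr(null_cohort, rng.permutation(carrier))
            logs.append(est.beta)
        assert abs(np.mean(logs)) < 3 * np.std(logs) / np.sqrt(len(logs)) + 0.05

    def test_zero_carriers_raise(self, null_cohort):
        with pytest.raises(sc.CoxFitError, match="no carriers"):
            sc.cox_carrier_hr(null_cohort, np.zeros(len(null_cohort)))

    def test_estimate_fields_are_consistent(self, null_cohort):
        rng = np.random.default_rng(6)
        carrier = (rng.random(len(null_cohort)) < 0.05).astype(float)
        est = sc.cox_carrier_hr(null_cohort, carrier)
        assert est.hr == pytest.approx(np.exp(est.beta))
        assert 0 < est.p <= 1
        assert est.n_carriers == int(carrier.sum())


class TestLastKnownAge:
    @pytest.mark.parametrize(
        "by, bm, censor, expected",
        [(1950, 11, (2022, 11), 72.0), (1950, 5, (2022, 11), 72.5)],
    )
    def test_month_resolution(self, by, bm, censor, expected):
        assert sc.last_known_age(by, bm, censor) == pytest.approx(expected)

    def test_birth_after_censor_raises(self):
        with pytest.raises(ValueError):
            sc.last_known_age(2023, 1, (2022, 11))
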