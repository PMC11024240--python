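"""Cox partial likelihood, Newton fitting, Breslow hazard and Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iuasurv.survival_core import (
    BaselineHazardCurve,
    CohortTable,
    ConvergenceError,
    InvalidScoreError,
    NoEventsError,
    SurvivalRecord,
    breslow_cumulative_hazard,
    deepsurv_loss,
    fit_linear_cox,
    kaplan_meier,
    negative_log_partial_likelihood,
    predicted_event_probability,
)
from conftest import simulate_ph_cohort


class TestPartialLikelihood:
    @pytest.mark.parametrize(
        "scores,times,events,expected",
        [
            ([0, 0, 0], [1, 2, 3], [1, 1, 1], np.log(6)),  # risk-set sizes 3,2,1
            ([5], [4], [1], 0.0),  # singleton risk set
            ([1, 0], [1, 2], [1, 1], np.log(np.exp(1) + 1) - 1),
        ],
    )
    def test_hand_computed_values(self, scores, times, events, expected):
        got = negative_log_partial_likelihood(scores, times, events)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_breslow_tie_handling(self):
        # two events at t=1 share the full risk set of 3: -2*(0 - log 3)
        got = negative_log_partial_likelihood([0, 0, 0], [1, 1, 2], [1, 1, 0])
        assert got == pytest.approx(2 * np.log(3), abs=1e-12)

    @given(
        shift=st.floats(-30, 30),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        n = 25
        s = rng.normal(size=n)
        t = rng.uniform(0.5, 20, n)
        e = (rng.uniform(size=n) < 0.7).astype(int)
        if e.sum() == 0:
            e[0] = 1
        a = negative_log_partial_likelihood(s, t, e)
        b = negative_log_partial_likelihood(s + shift, t, e)
        assert b == pytest.approx(a, abs=1e-9)

    def test_error_contracts(self):
        with pytest.raises(NoEventsError):
            negative_log_partial_likelihood([0, 0], [1, 2], [0, 0])
        with pytest.raises(InvalidScoreError):
            negative_log_partial_likelihood([np.nan, 0], [1, 2], [1, 1])
        with pytest.raises(InvalidScoreError):
            negative_log_partial_likelihood([np.inf, 0], [1, 2], [1, 1])
        with pytest.raises(ValueError):
            negative_log_partial_likelihood([0], [1, 2], [1, 1])


class TestDeepSurvLoss:
    def test_reduces_to_per_event_nll(self):
        s, t, e = [0.3, -0.2, 0.9], [1, 2, 3], [1, 0, 1]
        nll = negative_log_partial_likelihood(s, t, e)
        assert deepsurv_loss(s, t, e, 0.0, 0.0) == pytest.approx(nll / 2)

    def test_zero_scores_example(self):
        got = deepsurv_loss([0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert got == pytest.approx(np.log(6) / 3, abs=1e-10)

    def test_penalty_is_additive(self):
        s, t, e = [0.3, -0.2, 0.9], [1, 2, 3], [1, 0, 1]
        base = deepsurv_loss(s, t, e, weight_sq_norm=2.0, lam=0.0)
        reg = deepsurv_loss(s, t, e, weight_sq_norm=2.0, lam=0.5)
        assert reg - base == pytest.approx(1.0, abs=1e-12)


class TestLinearCox:
    def test_null_effect_binary_covariate(self):
        rng = np.random.default_rng(0)
        n = 600
        g = rng.integers(0, 2, n).astype(float)
        T = rng.exponential(10, n)
        C = rng.uniform(5, 40, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        m = fit_linear_cox(g.reshape(-1, 1), t, e)
        assert abs(m.beta[0]) < 2 * m.standard_errors[0]

    def test_parameter_recovery_and_coverage(self, ph_data_500):
        X, t, e = ph_data_500
        m = fit_linear_cox(X, t, e)
        assert m.beta[0] == pytest.approx(0.8, abs=0.15)
        lo, hi = np.log(m.confidence_intervals()[0])
        assert lo < 0.8 < hi

    def test_matches_reference_maximizer(self):
        """Cross-implementation oracle: 20 random censored instances."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(30, 80))
            X = rng.normal(size=(n, 2))
            b = rng.normal(0, 0.5, 2)
            T = rng.exponential(1.0 / (0.1 * np.exp(X @ b)))
            C = rng.uniform(2, 40, n)
            t = np.minimum(T, C)
            e = (T <= C).astype(int)
            if e.sum() < 3:
                continue
            mine = fit_linear_cox(X, t, e)
            df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]})
            ref = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-12})
            assert np.abs(mine.beta - ref.params_.values).max() < 1e-6

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_cox(np.ones((10, 1)), np.arange(1, 11), np.ones(10, int))

    def test_complete_separation_flagged(self):
        # perfectly ordered covariate with all events: monotone likelihood
        t = np.arange(1.0, 21.0)
        x = -t.reshape(-1, 1) / 100.0  # higher x -> strictly earlier event
        with pytest.raises(ConvergenceError):
            fit_linear_cox(x, t, np.ones(20, int))


class TestBreslowHazard:
    def test_two_subject_hand_case(self):
        c = breslow_cumulative_hazard([0, 0], [1, 2], [1, 1])
        assert np.allclose(c.times, [1, 2])
        assert np.allclose(c.cumulative_hazard, [0.5, 1.5])

    def test_score_shift_scales_increments(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=30)
        t = rng.uniform(1, 10, 30)
        e = (rng.uniform(size=30) < 0.7).astype(int)
        c0 = breslow_cumulative_hazard(s, t, e)
        c1 = breslow_cumulative_hazard(s + 2.0, t, e)
        assert np.allclose(c1.cumulative_hazard, c0.cumulative_hazard * np.exp(-2.0))

    def test_nelson_aalen_limit_exponential(self):
        rng = np.random.default_rng(2)
        lam = 0.2
        t = rng.exponential(1 / lam, 4000)
        e = np.ones(4000, int)
        c = breslow_cumulative_hazard(np.zeros(4000), t, e)
        for q in (2.0, 5.0, 8.0):
            assert c(q) == pytest.approx(lam * q, rel=0.08)

    def test_evaluates_zero_before_first_event(self):
        c = breslow_cumulative_hazard([0, 0], [5, 9], [1, 1])
        assert c(1.0) == 0.0


class TestEventProbability:
    def test_closed_forms(self):
        curve = BaselineHazardCurve(np.array([1.0]), np.array([np.log(2)]))
        assert predicted_event_probability(0.0, curve, 0.5) == 0.0  # before 1st event
        assert predicted_event_probability(0.0, curve, 2.0) == pytest.approx(0.5)

    def test_monotone_in_horizon_and_score(self):
        curve = BaselineHazardCurve(
            np.array([1.0, 5.0, 9.0]), np.array([0.1, 0.4, 0.9])
        )
        ps = [predicted_event_probability(0.3, curve, h) for h in (1, 5, 9, 12)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        qs = [predicted_event_probability(z, curve, 9.0) for z in (-1, 0, 1, 2)]
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps + qs)


class TestKaplanMeier:
    def test_uncensored_empirical_steps(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km([1, 2, 3, 4]), [0.75, 0.5, 0.25, 0.0])
        assert km(0.5) == 1.0

    def test_all_censored_is_flat_one(self):
        km = kaplan_meier([3, 6, 9], [0, 0, 0])
        assert km(100.0) == 1.0

    def test_matches_reference_implementation(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.uniform(0.5, 30, 200)
        e = (rng.uniform(size=200) < 0.6).astype(int)
        km = kaplan_meier(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(1, 29, 15)
        ref_vals = ref.survival_function_at_times(grid).values
        assert np.allclose(km(grid), ref_vals, atol=1e-10)

    def test_consistent_with_breslow_at_null_scores(self):
        """exp(-H0) and the product-limit curve agree to O(1/n)."""
        X, t, e = simulate_ph_cohort(500, [0.0], seed=7)
        km = kaplan_meier(t, e)
        c = breslow_cumulative_hazard(np.zeros(t.size), t, e)
        ev = np.unique(t[e == 1])
        gap = np.abs(np.exp(-c(ev)) - km(ev)).max()
        assert gap < 0.02


class TestDomainTypes:
    def test_record_invariants(self):
        with pytest.raises(ValueError):
            SurvivalRecord("p1", -1.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("p1", 5.0, 2)
        with pytest.raises(ValueError):
            SurvivalRecord("p1", 5.0, 0, art=3)

    def test_cohort_rejects_duplicates_and_ragged_covariates(self):
        r1 = SurvivalRecord("a", 1.0, 1, covariates=np.zeros(2))
        r2 = SurvivalRecord("a", 2.0, 0, covariates=np.zeros(2))
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable(records=[r1, r2])
        r3 = SurvivalRecord("b", 2.0, 0, covariates=np.zeros(3))
        with pytest.raises(ValueError, match="covariate"):
            CohortTable(records=[r1, r3])

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            BaselineHazardCurve(np.array([2.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            BaselineHazardCurve(np.array([1.0, 2.0]), np.array([0.2, 0.1]))
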