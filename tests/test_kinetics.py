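"""Two-step deactivation curve, fitting, model comparison and half-life."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from oracles import ode_alpha
from thermolipase.kinetics import (
    FirstOrderDeactivation, TimeCourse, TwoStepDeactivation,
    compare_models, fit_first_order, fit_two_step, half_life,
    read_timecourse_csv, residual_activity, write_timecourse_csv,
)


class TestResidualActivity:
    @pytest.mark.parametrize("params", [
        (0.0, 0.1, 0.01), (0.5, 0.3, 1e-4), (1.0, 2.0, 2.0), (0.647, 2.24e-2, 1.82e-4),
    ])
    def test_starts_at_one(self, params):
        assert residual_activity(0.0, *params) == pytest.approx(1.0, abs=1e-15)

    def test_alpha1_zero_collapses_to_single_exponential(self):
        t = np.linspace(0, 100, 7)
        np.testing.assert_allclose(
            residual_activity(t, 0.0, 0.05, 0.3), np.exp(-0.05 * t), rtol=1e-12)

    def test_reference_value_matches_ode_oracle(self, sp14_70_truth):
        # closed form at t = 60 min for the SP14/70degC triple
        val = residual_activity(60.0, **sp14_70_truth)
        assert val == pytest.approx(0.7358958805, abs=1e-9)
        oracle = ode_alpha(np.array([60.0]), **sp14_70_truth)[0]
        assert val == pytest.approx(oracle, abs=1e-10)

    def test_singular_branch_is_continuous(self):
        # approaching k2 = k1 from both sides agrees with the analytic limit
        k1, a1, t = 0.05, 0.6, np.linspace(0, 200, 11)
        limit = (1 + a1 * k1 * t) * np.exp(-k1 * t)
        for eps in (1 + 2e-8, 1 - 2e-8, 1 + 1e-9):
            np.testing.assert_allclose(
                residual_activity(t, a1, k1, k1 * eps), limit, atol=1e-7)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            residual_activity(-1.0, 0.5, 0.1, 0.01)
        with pytest.raises(ValueError):
            residual_activity(1.0, 1.5, 0.1, 0.01)
        with pytest.raises(ValueError):
            residual_activity(1.0, 0.5, -0.1, 0.01)

    @given(
        alpha1=st.floats(0.0, 1.0),
        k1=st.floats(1e-4, 10.0),
        ratio=st.floats(1e-4, 1.0),
        t=st.lists(st.floats(0.0, 500.0), min_size=2, max_size=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_curve_is_nonincreasing_and_bounded(self, alpha1, k1, ratio, t):
        ts = np.sort(np.asarray(t))
        vals = residual_activity(ts, alpha1, k1, k1 * ratio)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals <= 1.0 + 1e-12) and np.all(vals >= 0.0)


class TestTwoStepFit:
    def test_zero_noise_recovery_is_exact(self, sp14_70_truth):
        # identifiable design: points spanning both decay phases
        t = np.array([0, 10, 20, 40, 60, 90, 150, 400, 1500, 4000, 8000, 11000.0])
        y = residual_activity(t, **sp14_70_truth)
        p = fit_two_step((t, y), multistart=8, seed=0)
        assert p.alpha1 == pytest.approx(sp14_70_truth["alpha1"], rel=1e-6)
        assert p.k1 == pytest.approx(sp14_70_truth["k1"], rel=1e-6)
        assert p.k2 == pytest.approx(sp14_70_truth["k2"], rel=1e-6)
        assert p.ssr < 1e-16 and p.r2 > 1 - 1e-12

    def test_single_exponential_data_fits_with_zero_ssr(self):
        # nested-model limit: SSR is the contract, parameters sit on a ridge
        t = np.linspace(0, 60, 13)
        y = np.exp(-0.1 * t)
        p = fit_two_step((t, y), seed=1)
        assert p.ssr < 1e-12

    def test_too_few_distinct_times_rejected(self):
        t = np.array([0.0, 10.0, 20.0, 0.0, 10.0, 20.0])
        with pytest.raises(ValueError, match="4 distinct"):
            TwoStepDeactivation(t, np.exp(-0.1 * t))

    def test_results_object_reports_diagnostics(self, sp14_70_truth, rng):
        t = np.tile(np.array([0, 5, 15, 30, 60, 200, 1000, 5000, 10000.0]), 3)
        y = residual_activity(t, **sp14_70_truth) + rng.normal(0, 0.02, t.size)
        res = TwoStepDeactivation(t, y).fit(seed=2)
        assert res.nobs == t.size
        assert 0.9 < res.rsquared <= 1.0
        assert (res.bse > 0).all()
        text = res.summary()
        assert "alpha1" in text and "half-life" in text

    def test_replicates_via_timecourse_container(self, sp14_70_truth):
        t = np.array([0, 20, 60, 300, 2000, 8000.0])
        obs = pd.DataFrame({
            "time_min": np.tile(t, 2),
            "replicate": np.repeat([0, 1], t.size),
            "residual_activity": np.tile(residual_activity(t, **sp14_70_truth), 2),
        })
        tc = TimeCourse("SP14", 70.0, obs)
        p = fit_two_step(tc, seed=3)
        assert p.n_obs == 12
        assert p.alpha1 == pytest.approx(0.647, abs=1e-6)


class TestFirstOrderFit:
    def test_exact_recovery_on_noiseless_data(self):
        t = np.linspace(0, 100, 9)
        res = fit_first_order((t, np.exp(-0.05 * t)))
        assert res.k == pytest.approx(0.05, rel=1e-8)
        assert res.ssr < 1e-18
        # independent oracle: 1-D golden-section minimum of the SSR profile
        oracle = minimize_scalar(
            lambda k: np.sum((np.exp(-k * t) - np.exp(-0.05 * t)) ** 2),
            bounds=(1e-4, 1.0), method="bounded",
            options={"xatol": 1e-12})
        assert res.k == pytest.approx(oracle.x, abs=1e-6)

    def test_biphasic_data_fits_worse_than_two_step(self):
        t = np.linspace(0, 60, 13)
        y = residual_activity(t, 0.5, 0.3, 1e-4)
        one = fit_first_order((t, y))
        two = fit_two_step((t, y), seed=4)
        assert two.ssr < one.ssr  # nesting
        assert one.ssr > 1e-3

    def test_constant_data_flagged_non_identifiable(self):
        t = np.linspace(0, 60, 13)
        res = fit_first_order((t, np.ones_like(t)))
        assert res.non_identifiable
        assert "non-identifiable" in res.summary()

    def test_needs_two_distinct_times(self):
        with pytest.raises(ValueError):
            FirstOrderDeactivation(np.zeros(3), np.ones(3))


class TestCompareModels:
    def test_noiseless_biphasic_prefers_two_step_with_infinite_delta(self):
        t = np.linspace(0, 120, 13)
        y = residual_activity(t, 0.5, 0.3, 1e-3)
        cmp_ = compare_models((t, y), seed=5)
        assert cmp_.preferred == "two_step"
        assert np.isinf(cmp_.delta_aic)

    def test_delta_aic_sign_convention(self, sp14_70_truth, rng):
        t = np.tile(np.linspace(0, 8000, 13), 3)
        y = residual_activity(t, **sp14_70_truth) + rng.normal(0, 0.02, t.size)
        cmp_ = compare_models((t, y), seed=6)
        assert cmp_.delta_aic == pytest.approx(
            cmp_.first_order.aic - cmp_.two_step.aic)


class TestHalfLife:
    def test_single_exponential_closed_form(self):
        assert half_life((0.0, np.log(2) / 10.0, 1e-3)) == pytest.approx(10.0,
                                                                         rel=1e-10)

    def test_matches_bisection_oracle(self, sp14_70_truth):
        a1, k1, k2 = sp14_70_truth.values()
        lo, hi = 0.0, 1e9
        for _ in range(200):  # plain bisection to 1e-9 precision
            mid = 0.5 * (lo + hi)
            if residual_activity(mid, a1, k1, k2) > 0.5:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9:
                break
        assert half_life((a1, k1, k2)) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    @pytest.mark.parametrize("bump", ["k1", "k2"])
    def test_decreasing_in_each_rate_constant(self, bump):
        base = {"alpha1": 0.6, "k1": 0.05, "k2": 5e-4}
        faster = dict(base)
        faster[bump] *= 2.0
        assert (half_life(tuple(faster.values()))
                < half_life(tuple(base.values())))


class TestTimeCourseIO:
    def test_csv_roundtrip(self, tmp_path, sp14_70_truth):
        t = np.array([0.0, 5.0, 20.0, 60.0])
        tc = TimeCourse.from_arrays("SP14", 70.0, np.tile(t, 2),
                                    np.tile(residual_activity(t, **sp14_70_truth), 2),
                                    replicate=np.repeat([0, 1], t.size))
        path = tmp_path / "tc.csv"
        write_timecourse_csv([tc], path)
        back = read_timecourse_csv(path)
        assert len(back) == 1
        assert back[0].enzyme_id == "SP14" and back[0].temperature_c == 70.0
        np.testing.assert_allclose(back[0].activity, tc.activity)

    def test_negative_times_rejected(self):
        obs = pd.DataFrame({"time_min": [-1.0, 0.0], "replicate": 0,
                            "residual_activity": [1.0, 1.0]})
        with pytest.raises(ValueError):
            TimeCourse("x", 70.0, obs)
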