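"""Closed-form DDM: choice probability, decision times, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motorbias import ddm_core as dc

from conftest import SP_ROW, exact_condition_table, simulate_condition_table


def make_params(**kw) -> dc.DDMParams:
    base = dict(k=0.3, A=10.0, B=10.0, t0_left=400.0, t0_right=400.0)
    base.update(kw)
    return dc.DDMParams(**base)


class TestClosedForms:
    def test_drift_scales_with_coherence(self):
        p = make_params(k=0.29)
        assert dc.drift(p, 0.0, "baseline") == 0.0
        assert dc.drift(p, 0.512, "baseline") == pytest.approx(0.14848)

    def test_drift_sensory_shift_in_percent_points(self):
        # dcoh is expressed in %-coherence points and only acts in the test phase
        p = make_params(k=0.29, dcoh=4.00)
        assert dc.drift(p, 0.0, "test") == pytest.approx(0.29 * 0.04)
        assert dc.drift(p, 0.0, "baseline") == 0.0

    def test_p_right_symmetric_zero_drift(self):
        assert dc.p_right(make_params(), 0.0, "baseline") == pytest.approx(0.5)

    def test_p_right_zero_drift_limit_with_start_shift(self):
        # b'/(a'+b') with bounds shifted by the starting point
        p = make_params(k=1.0, A=10.0, B=10.0, sp=-1.62)
        assert dc.p_right(p, 0.0, "test") == pytest.approx((10 - 1.62) / 20.0, abs=1e-9)

    def test_p_right_group_parameters_strong_motion(self, sp_params):
        assert dc.p_right(sp_params, 0.512, "baseline") == pytest.approx(0.9727, abs=5e-4)

    def test_mean_decision_time_zero_drift_limit(self):
        # ((a+b)^2 - b^2)/3 = 1 for a = b = 1
        p = dc.DDMParams(k=1.0, A=1.0, B=1.0, t0_left=0.0, t0_right=0.0)
        assert dc.mean_decision_time(p, 0.0, "baseline", "right") == pytest.approx(1.0)

    def test_mean_decision_time_group_parameters(self, sp_params):
        t = dc.mean_decision_time(sp_params, 0.512, "baseline", "right")
        assert t == pytest.approx(74.78, abs=0.05)

    def test_predict_rt_composes_decision_and_nondecision(self, sp_params):
        dt = dc.mean_decision_time(sp_params, 0.512, "baseline", "right")
        rt = dc.predict_mean_rt_correct(sp_params, 0.512, "baseline")
        assert rt == pytest.approx(dt + sp_params.t0_right)

    def test_test_phase_nondecision_reductions_apply(self, sp_params):
        base = dc.nondecision_time(sp_params, "baseline", "right")
        test = dc.nondecision_time(sp_params, "test", "right")
        assert test - base == pytest.approx(sp_params.dt_right)

    def test_zero_deltas_make_phases_identical(self):
        p = make_params()
        cohs = np.array([-0.256, -0.032, 0.064, 0.512])
        np.testing.assert_allclose(dc.p_right(p, cohs, "test"),
                                   dc.p_right(p, cohs, "baseline"))
        np.testing.assert_allclose(dc.predict_mean_rt_correct(p, cohs, "test"),
                                   dc.predict_mean_rt_correct(p, cohs, "baseline"))

    def test_normalized_sp(self, sp_params):
        assert dc.normalized_sp(sp_params) == pytest.approx(-1.62 / (11.76 + 12.02))
        assert dc.normalized_sp(make_params(sp=0.0)) == 0.0
        assert dc.normalized_sp(make_params(sp=1.0, A=12.0, B=8.0)) == pytest.approx(0.05)

    def test_invalid_effective_bounds_rejected(self):
        p = make_params(A=2.0, B=10.0, sp=2.5)  # A - sp < 0 in test phase
        with pytest.raises(ValueError):
            dc.DDMParams(k=0.3, A=2.0, B=10.0, t0_left=0, t0_right=0, sp=2.5).validate()
        with pytest.raises(ValueError):
            dc.p_right(p, 0.1, "test")


class TestNumerics:
    def test_p_right_continuous_across_series_threshold(self):
        p = make_params(k=1.0, A=11.0, B=13.0)
        mus = np.array([1e-9, 1e-6, 4e-6, 5e-6, 1e-5, 1e-3])
        vals = dc.p_right(p, mus, "baseline")
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals) > 0)  # strictly increasing through the seam
        assert vals[0] == pytest.approx(13.0 / 24.0, abs=1e-6)

    def test_p_right_extreme_drift_saturates_without_overflow(self):
        p = make_params(k=1.0, A=30.0, B=30.0)
        with np.errstate(all="raise"):
            hi = dc.p_right(p, 0.999, "baseline")
            lo = dc.p_right(p, -0.999, "baseline")
        assert 0.0 < lo < 1e-10 and hi == pytest.approx(1.0, abs=1e-12)

    def test_decision_time_continuous_and_positive_near_zero_drift(self):
        p = make_params(k=1.0, A=11.76, B=12.02)
        cohs = np.array([1e-8, 1e-5, 4e-5, 5e-5, 1e-4, 1e-2])
        t = dc.mean_decision_time(p, cohs, "baseline", "right")
        assert np.all(np.isfinite(t)) and np.all(t > 0)
        assert np.ptp(t[:5]) < 1e-3  # flat in the deep small-drift regime

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(k=st.floats(0.05, 1.0), a=st.floats(2.0, 25.0), b=st.floats(2.0, 25.0),
           sp=st.floats(-1.5, 1.5), coh=st.floats(-0.6, 0.6))
    def test_choice_probability_properties(self, k, a, b, sp, coh):
        p = dc.DDMParams(k=k, A=a, B=b, t0_left=300, t0_right=300, sp=sp)
        pr = dc.p_right(p, coh, "test")
        assert 0.0 < pr < 1.0
        # complement through the left/right mirror
        pl = 1.0 - dc.p_right(dc.mirror_params(p), -coh, "test")
        assert pr == pytest.approx(pl, abs=1e-12)
        # monotone in drift and in the starting-point shift
        assert dc.p_right(p, coh + 0.05, "test") > pr
        p_up = dc.DDMParams(k=k, A=a, B=b, t0_left=300, t0_right=300, sp=sp + 0.3)
        assert dc.p_right(p_up, coh, "test") > pr

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(k=st.floats(0.05, 1.0), a=st.floats(2.0, 25.0), b=st.floats(2.0, 25.0),
           coh=st.floats(0.01, 0.6))
    def test_decision_time_mirror_symmetry(self, k, a, b, coh):
        p = dc.DDMParams(k=k, A=a, B=b, t0_left=0, t0_right=0)
        m = dc.mirror_params(p)
        t_right = dc.mean_decision_time(p, coh, "baseline", "right")
        t_left_mirror = dc.mean_decision_time(m, -coh, "baseline", "left")
        assert t_right == pytest.approx(t_left_mirror, rel=1e-12)


class TestLikelihoodAndFit:
    def test_nll_minimal_at_generating_parameters_on_grid(self, sp_params):
        data = exact_condition_table(sp_params, n_per_cell=5000)
        nll0 = dc.negative_log_likelihood(sp_params, "starting_point", data)
        rng = np.random.default_rng(0)
        for _ in range(12):
            scale = 1.0 + rng.uniform(-0.15, 0.15, size=4)
            pert = dc.DDMParams(k=sp_params.k * scale[0], A=sp_params.A * scale[1],
                                B=sp_params.B * scale[2],
                                t0_left=sp_params.t0_left, t0_right=sp_params.t0_right,
                                dt_left=sp_params.dt_left, dt_right=sp_params.dt_right,
                                sp=sp_params.sp * scale[3])
            assert dc.negative_log_likelihood(pert, "starting_point", data) > nll0

    def test_variant_contract_rejects_fixed_deltas(self, sp_params):
        data = exact_condition_table(sp_params, n_per_cell=100)
        with pytest.raises(ValueError):
            dc.negative_log_likelihood(sp_params, "sensory_evidence", data)

    def test_likelihood_scales_with_trial_counts(self, sp_params):
        # doubling every n doubles the binomial log-likelihood gap
        data = exact_condition_table(sp_params, n_per_cell=1000, sd_rt=np.nan)
        other = dc.DDMParams(k=0.32, A=11.76, B=12.02, t0_left=460, t0_right=459,
                             dt_left=-9.0, dt_right=-28.0, sp=-1.62)
        gap1 = (dc.negative_log_likelihood(other, "starting_point", data)
                - dc.negative_log_likelihood(sp_params, "starting_point", data))
        double = data.assign(n=data["n"] * 2, n_right=data["n_right"] * 2)
        gap2 = (dc.negative_log_likelihood(other, "starting_point", double)
                - dc.negative_log_likelihood(sp_params, "starting_point", double))
        assert gap2 == pytest.approx(2.0 * gap1, rel=0.02)

    def test_zero_coherence_rejected(self, sp_params):
        data = exact_condition_table(sp_params, n_per_cell=100)
        bad = pd.concat([data, pd.DataFrame([{
            "phase": "baseline", "coherence": 0.0, "n": 100, "n_right": 50,
            "mean_rt_correct": 500.0, "sd_rt_correct": 50.0}])])
        with pytest.raises(ValueError):
            dc.negative_log_likelihood(sp_params, "starting_point", bad)

    def test_fit_recovers_exact_data(self, sp_params):
        data = exact_condition_table(sp_params, n_per_cell=20_000, sd_rt=40.0)
        fr = dc.fit(data, "starting_point", n_starts=8, seed=3)
        assert fr.converged
        assert fr.params.k == pytest.approx(sp_params.k, rel=0.05)
        assert fr.params.A == pytest.approx(sp_params.A, rel=0.05)
        assert fr.params.B == pytest.approx(sp_params.B, rel=0.05)
        assert fr.params.sp == pytest.approx(sp_params.sp, abs=0.25)

    def test_fit_deterministic_given_seed(self, sp_sim_conditions):
        f1 = dc.fit(sp_sim_conditions, "baseline", n_starts=4, seed=9)
        f2 = dc.fit(sp_sim_conditions, "baseline", n_starts=4, seed=9)
        assert f1.nll == f2.nll and f1.params == f2.params

    def test_bic_bookkeeping(self, sp_sim_conditions):
        fr = dc.fit(sp_sim_conditions, "baseline", n_starts=4, seed=9)
        expected = 2.0 * fr.nll + fr.variant.n_params * np.log(fr.n_obs)
        assert fr.bic == pytest.approx(expected)
        assert fr.n_obs == dc.count_data_points(sp_sim_conditions)

    def test_variant_parameter_counts(self):
        counts = {v.name: v.n_params for v in dc.VARIANTS.values()}
        assert counts == {"baseline": 7, "starting_point": 8,
                          "sensory_evidence": 8, "full": 9}
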