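"""The measurement chain: windows, fits and statistics."""

import numpy as np
import pytest

from rodribbon.analysis import (baseline_deltas, compare_groups,
                                fit_activation, fit_dcm_vs_q,
                                fit_inactivation, fit_iv_curve,
                                fit_pool_depletion, measure_delta_cm,
                                measure_tail)
from rodribbon.channels import boltzmann_iv
from rodribbon.lockin import LockinTrace, SinewaveSpec


def _make_lockin(c_m_fF, dt_bin=0.5):
    n = c_m_fF.size
    t = (np.arange(n) + 0.5) * dt_bin
    return LockinTrace(times_ms=t, c_m_fF=c_m_fF,
                       g_m_nS=np.full(n, 0.5), g_s_nS=np.full(n, 33.7),
                       valid=np.ones(n, dtype=bool),
                       stimulation=np.zeros(n, dtype=bool),
                       spec=SinewaveSpec())


class TestMeasureDeltaCm:
    def test_programmed_step_recovered(self):
        cm = np.full(600, 1020.0)
        cm[300:] += 3.27
        tr = _make_lockin(cm)
        out = measure_delta_cm(tr, 149.9, 150.1, egta_mM=10.0)
        assert out["delta_cm_fF"] == pytest.approx(3.27, abs=0.05)
        assert out["delta_gm_nS"] == pytest.approx(0.0, abs=1e-9)

    def test_no_stimulation_measures_zero(self):
        tr = _make_lockin(np.full(600, 1020.0))
        out = measure_delta_cm(tr, 149.9, 150.1, egta_mM=10.0)
        assert out["delta_cm_fF"] == pytest.approx(0.0, abs=1e-9)

    def test_low_egta_delay_avoids_relaxing_tail_bias(self):
        """With a conductance tail decaying after the step, the 75 ms
        delayed window is unbiased while an immediate window is not."""
        cm = np.full(800, 1020.0)
        t = (np.arange(800) + 0.5) * 0.5
        step_end = 200.0
        cm[t >= step_end] += 3.27
        # artifactual C_m transient from the Cl(Ca) conductance tail
        tail = 5.0 * np.exp(-(t - step_end) / 15.0)
        cm = cm + np.where(t >= step_end, tail, 0.0)
        tr = _make_lockin(cm)
        delayed = measure_delta_cm(tr, 199.9, step_end, egta_mM=0.5)
        immediate = measure_delta_cm(tr, 199.9, step_end, egta_mM=10.0)
        assert delayed["delta_cm_fF"] == pytest.approx(3.27, abs=0.07)
        assert immediate["delta_cm_fF"] > 3.27 + 0.5  # biased by the tail

    def test_insufficient_bins_rejected(self):
        tr = _make_lockin(np.full(60, 1020.0))
        with pytest.raises(ValueError):
            measure_delta_cm(tr, 15.0, 15.5, egta_mM=10.0)


class TestBaselineDeltas:
    def test_stationary_sweep_is_zero(self):
        tr = _make_lockin(np.full(200, 1020.0))
        assert baseline_deltas(tr, [0.0])[0] == pytest.approx(0.0, abs=1e-9)

    def test_linear_drift_measured(self):
        t = (np.arange(200) + 0.5) * 0.5
        drift = 0.05  # fF per ms
        tr = _make_lockin(1020.0 + drift * t)
        # windows centered at 10 and 90 ms -> 80 ms apart
        assert baseline_deltas(tr, [0.0])[0] == pytest.approx(80 * drift,
                                                              rel=1e-6)

    def test_matches_window_average_oracle(self, rng):
        cm = 1020.0 + np.cumsum(rng.normal(0, 0.05, 200))
        tr = _make_lockin(cm)
        t = tr.times_ms
        oracle = (cm[(t >= 85) & (t < 95)].mean()
                  - cm[(t >= 5) & (t < 15)].mean())
        assert baseline_deltas(tr, [0.0])[0] == pytest.approx(oracle)

    def test_short_sweep_rejected(self):
        tr = _make_lockin(np.full(100, 1020.0))
        with pytest.raises(ValueError):
            baseline_deltas(tr, [20.0])


class TestFitActivation:
    dt = 0.02

    def _trace(self, tau, amp=-12.0, delay=0.25, n_ms=12.0, step0=5.0):
        t = np.arange(0, n_ms, self.dt)
        rel = t - step0 - delay
        i = np.where(rel > 0, amp * (1 - np.exp(-rel / tau)), 0.0)
        return t, i

    @pytest.mark.parametrize("tau", [0.16, 0.31, 0.55, 1.09])
    def test_parameter_recovery_within_1pct(self, tau):
        t, i = self._trace(tau)
        res = fit_activation(t, i, 5.0, 15.0)
        assert res.converged
        assert res.params["tau_activ_ms"] == pytest.approx(tau, rel=0.01)
        assert res.params["peak_i_pA"] == pytest.approx(-12.0, rel=0.01)

    def test_flat_trace_flagged_not_raised(self):
        t = np.arange(0, 12, self.dt)
        res = fit_activation(t, np.zeros_like(t), 5.0, 15.0)
        assert not res.converged
        assert res.message

    def test_short_window_flagged(self):
        t, i = self._trace(0.5)
        res = fit_activation(t, i, 5.0, 5.3)
        assert not res.converged


class TestMeasureTail:
    def test_no_step_no_tail(self):
        t = np.arange(0, 30, 0.02)
        assert measure_tail(t, np.zeros_like(t), 15.0) == 0.0

    def test_tail_amplitude_recovered(self):
        t = np.arange(0, 30, 0.02)
        i = np.where(t > 15.0, -20.0 * np.exp(-(t - 15.0) / 0.2), -5.0)
        i[t <= 15.0] = np.where(t[t <= 15.0] > 5, -5.0, 0.0)
        tail = measure_tail(t, i, 15.0)
        assert tail == pytest.approx(-20.0, rel=0.12)

    def test_trace_too_short_rejected(self):
        t = np.arange(0, 10, 0.02)
        with pytest.raises(ValueError):
            measure_tail(t, np.zeros_like(t), 9.5)


class TestFitInactivation:
    dt = 0.02

    @pytest.mark.parametrize("tau", [5.0, 20.0, 50.0])
    def test_recovery_grid_within_1pct(self, tau):
        t = np.arange(0, 300, self.dt)
        i = -13.2 + 4.0 * (1 - np.exp(-t / tau))
        res = fit_inactivation(t, i, (0.0, 300.0))
        assert res.converged
        assert res.params["tau_inact_ms"] == pytest.approx(tau, rel=0.01)

    def test_constant_trace_has_no_decay(self):
        t = np.arange(0, 100, self.dt)
        res = fit_inactivation(t, np.full_like(t, -9.0), (0.0, 100.0))
        assert not res.converged


class TestFitIvCurve:
    def _points(self, wt):
        v = np.arange(-80.0, 31.0, 10.0)
        return v, boltzmann_iv(v, wt.cav, "modified")

    def test_modified_recovers_generating_parameters(self, wt):
        v, i = self._points(wt)
        res = fit_iv_curve(v, i, "modified")
        assert res.converged
        assert res.params["v_half"] == pytest.approx(-24.0, rel=0.01)
        assert res.params["k"] == pytest.approx(-6.2, rel=0.01)
        assert res.params["v_rev"] == pytest.approx(44.6, rel=0.01)
        assert res.params["g_max"] == pytest.approx(0.30, rel=0.01)

    def test_simple_form_half_maximum_near_reported(self, wt):
        """The plain-sigmoid fit over the I-V foot puts half-maximal
        current near -28.7 mV."""
        v, i = self._points(wt)
        res = fit_iv_curve(v, i, "simple")
        assert res.converged
        assert res.params["v_half"] == pytest.approx(-28.7, abs=1.5)

    def test_symmetric_sigmoid_midpoint(self):
        v = np.arange(-60.0, 1.0, 5.0)
        i = -10.0 / (1 + np.exp((v + 30.0) / -5.0))
        res = fit_iv_curve(v, i, "simple")
        assert res.params["v_half"] == pytest.approx(-30.0, abs=0.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_iv_curve([0, 1, 2], [0, 1, 2], "modified")


class TestFitPoolDepletion:
    def test_exact_recovery_of_generating_curve(self):
        t = np.array([0.5, 1.0, 3.0, 9.0])
        y = 3.27 * (1 - np.exp(-t / 0.348))
        res = fit_pool_depletion(t, y, with_delay=False)
        assert res.params["amplitude_fF"] == pytest.approx(3.27, rel=1e-4)
        assert res.params["tau_ms"] == pytest.approx(0.348, rel=1e-3)

    def test_delayed_curve_recovered_with_delay_term(self):
        t = np.array([0.5, 1.0, 3.0, 6.0, 9.0])
        y = 3.27 * np.clip(1 - np.exp(-(t - 0.4) / 0.35), 0, None)
        res = fit_pool_depletion(t, y)
        assert res.params["tau_ms"] == pytest.approx(0.35, rel=0.02)
        assert res.params["t0_ms"] == pytest.approx(0.4, abs=0.02)

    def test_all_zero_gives_zero_amplitude(self):
        res = fit_pool_depletion([0.5, 1, 3, 9], np.zeros(4))
        assert res.params["amplitude_fF"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_pool_depletion([1.0, 3.0], [1.0, 2.0])


class TestFitDcmVsQ:
    def test_exact_recovery(self):
        q = np.array([0.5, 2.0, 5.0, 12.0, 40.0])
        y = 3.31 * (1 - np.exp(-q / 4.66))
        res = fit_dcm_vs_q(q, y)
        assert res.params["amplitude_fF"] == pytest.approx(3.31, rel=1e-4)
        assert res.params["q_e_fC"] == pytest.approx(4.66, rel=1e-3)

    def test_origin_consistency(self):
        q = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        y = 3.31 * (1 - np.exp(-q / 4.66))
        res = fit_dcm_vs_q(q, y)
        fitted_at_zero = res.params["amplitude_fF"] * (1 - np.exp(0.0))
        assert fitted_at_zero == 0.0

    def test_low_egta_long_steps_excluded(self):
        q = np.array([1.0, 3.0, 8.0, 20.0, 500.0])
        y = 3.31 * (1 - np.exp(-q / 4.66))
        y[-1] = 10.0  # corrupted long-step point under weak buffering
        res = fit_dcm_vs_q(q, y, durations_ms=[0.5, 1, 3, 3, 9],
                           egta_mM=[0.5] * 5)
        assert res.params["q_e_fC"] == pytest.approx(4.66, rel=1e-3)

    def test_exclusion_can_empty_the_fit(self):
        with pytest.raises(ValueError):
            fit_dcm_vs_q([1, 2, 3], [1, 2, 3], durations_ms=[9, 15, 30],
                         egta_mM=[0.5, 0.5, 0.5])


class TestCompareGroups:
    def test_identical_samples(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p"] == pytest.approx(1.0)
        assert out["mean_a"] == out["mean_b"]

    def test_matches_hand_computed_t_statistic(self):
        """Textbook two-sample case with the pooled-variance formula."""
        a = np.array([4.0, 5.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        out = compare_groups(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out["t"] == pytest.approx(t_hand)

    def test_se_is_sd_over_sqrt_n(self):
        a = np.array([2.0, 4.0, 6.0, 8.0])
        out = compare_groups(a, a + 1)
        assert out["se_a"] == pytest.approx(a.std(ddof=1) / 2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
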