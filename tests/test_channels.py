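"""Ca_v1.4 current model: Boltzmann forms, kinetics, charge utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodribbon.channels import (CavParams, ClCaParams, boltzmann_iv,
                                charge_to_ions, integrate_qca, simulate_ica,
                                simulate_icl, tau_activation)


class TestBoltzmannIV:
    def test_zero_at_reversal_potential(self, wt):
        assert boltzmann_iv(wt.cav.v_rev_mV, wt.cav, "modified") == \
            pytest.approx(0.0, abs=1e-12)

    def test_reported_curve_value_at_minus_10(self, wt):
        """Direct evaluation of the fitted curve parameters at -10 mV."""
        assert boltzmann_iv(-10.0, wt.cav, "modified") == \
            pytest.approx(-14.8, abs=0.1)

    def test_asymptotically_linear_at_depolarized_voltages(self, wt):
        v = np.array([100.0, 200.0])
        i = boltzmann_iv(v, wt.cav, "modified")
        slope = (i[1] - i[0]) / 100.0
        assert slope == pytest.approx(wt.cav.g_max_pA_per_mV, rel=1e-3)

    def test_simple_form_midpoint(self, wt):
        val = boltzmann_iv(wt.cav.v_half_mV, wt.cav, "simple",
                           i_min=-14.0, i_max=0.0)
        assert val == pytest.approx(-7.0)

    def test_zero_slope_rejected(self, wt):
        import dataclasses
        bad = dataclasses.replace(wt.cav, slope_mV=0.0)
        with pytest.raises(ValueError):
            boltzmann_iv(-10.0, bad)


class TestTauActivation:
    @pytest.mark.parametrize("v, egta, expected", [
        (-30.0, 10.0, 1.09),
        (-20.0, 10.0, 0.489),
        (0.0, 10.0, 0.18),
        (-30.0, 0.5, 0.55),
        (-20.0, 0.5, 0.310),
        (0.0, 0.5, 0.16),
    ])
    def test_anchor_values_exact(self, v, egta, expected):
        assert tau_activation(v, egta) == pytest.approx(expected, rel=1e-12)

    def test_sixfold_slowing_at_high_egta(self):
        assert tau_activation(-30, 10.0) / tau_activation(0, 10.0) == \
            pytest.approx(6.06, abs=0.01)

    @pytest.mark.parametrize("v", np.arange(-40.0, 0.5, 2.5).tolist())
    def test_facilitation_direction(self, v):
        """Weak buffering never slows activation (facilitation)."""
        assert tau_activation(v, 0.5) <= tau_activation(v, 10.0) + 1e-12

    def test_monotone_decreasing_with_depolarization(self):
        for egta in (0.5, 10.0):
            taus = [tau_activation(v, egta) for v in np.arange(-40, 1, 1.0)]
            assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_out_of_range_voltage_rejected(self):
        with pytest.raises(ValueError):
            tau_activation(-50.0, 10.0)

    def test_ko_preset_loses_facilitation(self, ko):
        """Without the ribbon both buffering conditions use the fast set."""
        assert tau_activation(-30.0, 10.0, ko.cav) == \
            tau_activation(-30.0, 0.5, ko.cav) == pytest.approx(0.55)


class TestSimulateIca:
    dt = 0.02

    def _step_trace(self, v_step, dur_ms, params, egta=10.0, pre=5.0,
                    post=5.0):
        n_pre = int(pre / self.dt)
        n_step = int(dur_ms / self.dt)
        n_post = int(post / self.dt)
        v = np.concatenate([np.full(n_pre, -70.0), np.full(n_step, v_step),
                            np.full(n_post, -70.0)])
        t = np.arange(v.size) * self.dt
        return t, v, simulate_ica(v, self.dt, params, egta)

    def test_holding_at_rest_produces_no_current(self, wt):
        v = np.full(2000, -70.0)
        i = simulate_ica(v, self.dt, wt.cav, 10.0)
        assert np.all(np.abs(i) < 0.05)

    def test_peak_at_minus18_matches_initial_peak_of_long_steps(self, wt):
        """Reported 200 ms steps to -18 mV peak at -13.2 +/- 0.8 pA."""
        t, _, i = self._step_trace(-18.0, 200.0, wt.cav, pre=5, post=2)
        during = i[(t > 5) & (t < 204.9)]
        assert abs(during.min() - (-13.2)) <= 0.8

    def test_31pct_decay_with_19p46ms_tau(self, wt):
        t, v, i = self._step_trace(-18.0, 200.0, wt.cav, pre=5, post=2)
        during = i[(t > 5) & (t < 204.9)]
        peak = during.min()
        end = np.mean(i[(t > 200) & (t < 204.9)])
        assert 1 - end / peak == pytest.approx(0.31, abs=0.015)

    def test_current_onset_delayed(self, wt):
        t, v, i = self._step_trace(-18.0, 3.0, wt.cav)
        on = t[np.flatnonzero(np.abs(i) > 0.2)[0]]
        assert 5.0 + wt.cav.activation_delay_ms <= on <= 5.0 + 0.35

    def test_tail_decays_within_1ms_of_repolarization(self, wt):
        t, v, i = self._step_trace(-18.0, 3.0, wt.cav)
        after = np.abs(i[(t > 9.0) & (t < 10.0)])  # 1 ms past repol
        assert np.all(after < 0.05 * np.max(np.abs(i)))

    def test_no_vdi_limit_gives_flat_plateau(self, wt):
        import dataclasses
        p = dataclasses.replace(wt.cav, inact_fraction=0.0)
        t, v, i = self._step_trace(-18.0, 100.0, p)
        plateau = i[(t > 15) & (t < 104)]
        assert np.ptp(plateau) < 0.01 * np.abs(plateau).max()

    def test_tail_integral_bounded(self, wt):
        """Tail charge cannot exceed G_max |V_hold - V_rev| tau_deactiv."""
        t, v, i = self._step_trace(-10.0, 10.0, wt.cav)
        tail = np.abs(i[(t > 15.0) & (t < 17.0)])
        q_tail = np.trapezoid(tail, dx=self.dt)
        bound = wt.cav.g_max_pA_per_mV * (70 + wt.cav.v_rev_mV) \
            * wt.cav.tau_deactiv_ms
        assert q_tail <= bound * 1.05


class TestSimulateIcl:
    dt = 0.02

    def _trace(self, egta, dur=10.0, v_step=-18.0):
        n = int(40 / self.dt)
        v = np.full(n, -70.0)
        a, b = int(10 / self.dt), int((10 + dur) / self.dt)
        v[a:b] = v_step
        cl = ClCaParams.for_egta(egta)
        return np.arange(n) * self.dt, v, simulate_icl(v, self.dt, cl)

    def test_blocked_by_10mM_egta(self):
        _, _, i = self._trace(10.0)
        assert np.all(i == 0.0)

    def test_outward_during_step_inward_tail_at_rest(self):
        t, v, i = self._trace(0.5)
        during = i[(t > 15) & (t < 19.9)]
        tail = i[(t > 20.1) & (t < 24)]
        assert during.max() > 0.5
        assert tail.min() < -10.0

    def test_no_calcium_entry_no_chloride_current(self):
        _, _, i = self._trace(0.5, v_step=-65.0)
        assert np.allclose(i, 0.0, atol=1e-6)

    def test_tail_tracks_normalized_peak_ica(self, wt):
        """Across step voltages the Cl tail scales with peak I_Ca."""
        tails, peaks = [], []
        for v_step in (-40.0, -30.0, -20.0, -10.0):
            t, v, i = self._trace(0.5, v_step=v_step)
            tails.append(-i[(t > 20.05) & (t < 22)].min())
            peaks.append(abs(float(wt.cav.i_inf(v_step))))
        ratios = np.array(tails) / np.array(peaks)
        assert np.ptp(ratios) < 0.15 * ratios.mean()


class TestChargeUtilities:
    def test_rectangle(self):
        i = np.full(51, -10.0)
        assert integrate_qca(i, dt_ms=0.02) == pytest.approx(10.0, rel=1e-9)

    def test_zero_trace(self):
        assert integrate_qca(np.zeros(100), dt_ms=0.02) == 0.0

    def test_matches_fine_grid_riemann_oracle(self, rng):
        t = np.arange(0, 5, 0.02)
        i = -10 * np.exp(-t / 0.7) * (1 + 0.2 * np.sin(7 * t))
        q = integrate_qca(i, dt_ms=0.02)
        # refinement oracle: midpoint Riemann sum on a 100x finer grid
        tf = np.arange(0, t[-1], 0.0002) + 0.0001
        i_f = -10 * np.exp(-tf / 0.7) * (1 + 0.2 * np.sin(7 * tf))
        q_oracle = abs(np.sum(i_f) * 0.0002)
        assert q == pytest.approx(q_oracle, rel=1e-3)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            integrate_qca(np.zeros(100), dt_ms=0.02, window_ms=(1.0, 3.0))

    @pytest.mark.parametrize("q_fC, ions", [
        (4.66, 12263),   # the e-fold depletion charge
        (0.0, 0),
        (3.8e-4, 1),     # a single ion's worth of charge
    ])
    def test_charge_to_ions(self, q_fC, ions):
        assert charge_to_ions(q_fC) == ions

    def test_negative_charge_rejected(self):
        with pytest.raises(ValueError):
            charge_to_ions(-1.0)
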