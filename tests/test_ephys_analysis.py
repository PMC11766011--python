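import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdgate import ephys_analysis as ea
from vsdgate import ephys_synth as es


def boltzmann_activation(v, v_half, k):
    return 1.0 / (1.0 + np.exp((v_half - v) / k))


class TestSweepFeatures:
    def test_analytic_peak_location(self):
        t = np.arange(0, 10, 0.05)
        current = -t * np.exp(1 - t)   # peak -1 pA at t = 1 ms
        f = ea.sweep_features(t, current)
        assert f.peak_current == pytest.approx(-1.0, abs=1e-3)
        assert f.time_to_peak == pytest.approx(1.0, abs=0.05)

    def test_decay50_closed_form(self):
        t = np.arange(0, 20, 0.05)
        current = -100.0 * np.exp(-t / 2.0)  # instant peak, tau = 2 ms
        f = ea.sweep_features(t, current)
        assert f.decay50 == pytest.approx(2.0 * math.log(2.0), abs=0.05)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0])
    def test_decay50_tau_range(self, tau):
        t = np.arange(0, 20 * tau, 0.05)
        f = ea.sweep_features(t, -50.0 * np.exp(-t / tau))
        assert f.decay50 == pytest.approx(tau * math.log(2.0), abs=0.05)

    def test_monotone_growth_undefined_decay(self):
        t = np.arange(0, 10, 0.05)
        f = ea.sweep_features(t, -t)
        assert f.decay50 is None
        assert f.defined

    def test_all_zero_flagged(self):
        t = np.arange(0, 10, 0.05)
        f = ea.sweep_features(t, np.zeros_like(t))
        assert not f.defined

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ea.sweep_features(np.arange(5.0), np.arange(5.0))


class TestIVCurve:
    def _traces(self, peaks):
        proto = es.ProtocolSpec.iv()
        t = np.arange(0, 40.0001, 0.05)
        sweeps = {v: np.full_like(t, p) for v, p in peaks.items()}
        for v in sweeps:
            sweeps[v][0] = 0.0
        return es.TraceSet(proto, t, sweeps, {}, None)

    def test_density_division(self):
        traces = self._traces({-20.0: -300.0})
        iv = ea.iv_curve(traces, 10.0)
        assert iv.densities[0] == pytest.approx(-30.0)

    def test_density_linearity(self):
        traces = self._traces({-20.0: -300.0, 0.0: -100.0})
        d1 = ea.iv_curve(traces, 10.0).densities
        d2 = ea.iv_curve(traces, 20.0).densities
        np.testing.assert_allclose(d1, 2 * d2)

    def test_invalid_capacitance(self):
        with pytest.raises(ValueError):
            ea.iv_curve(self._traces({0.0: 1.0}), 0.0)

    def test_zero_density_at_reversal(self):
        p = es.preset_params("WT", "IV")
        traces = es.simulate_protocol(p, es.ProtocolSpec.iv(), seed=0)
        iv = ea.iv_curve(traces, 9.0)
        assert iv.densities[list(iv.voltages).index(p.v_rev)] == pytest.approx(0.0)


class TestEstimateVrev:
    def _iv(self, voltages, peaks):
        v = np.asarray(voltages, dtype=float)
        p = np.asarray(peaks, dtype=float)
        return ea.IVCurve(v, p, p / 10.0, 10.0)

    def test_midpoint_interpolation(self):
        iv = self._iv([25.0, 35.0, 45.0], [-30.0, -10.0, 10.0])
        assert ea.estimate_vrev(iv) == pytest.approx(40.0)

    def test_exact_zero_grid_point(self):
        iv = self._iv([30.0, 40.0, 50.0], [-10.0, 0.0, 10.0])
        assert ea.estimate_vrev(iv) == pytest.approx(40.0)

    def test_all_inward_raises(self):
        iv = self._iv([0.0, 10.0, 20.0], [-30.0, -20.0, -10.0])
        with pytest.raises(ValueError, match="v_rev"):
            ea.estimate_vrev(iv)


class TestConductanceCurve:
    def test_chord_transform_value(self):
        iv = ea.IVCurve(np.array([-20.0, 0.0]), np.array([-300.0, -200.0]),
                        np.array([-30.0, -20.0]), 10.0)
        curve = ea.conductance_curve(iv, 40.0)
        assert curve["g_nS"].iloc[0] == pytest.approx(5.0)  # -300 / -60

    def test_all_zero_flagged(self):
        iv = ea.IVCurve(np.array([-20.0, 0.0]), np.zeros(2), np.zeros(2), 10.0)
        curve = ea.conductance_curve(iv, 40.0)
        np.testing.assert_allclose(curve["g_norm"], 0.0)

    def test_near_vrev_points_dropped(self):
        iv = ea.IVCurve(np.array([30.0, 37.0, 50.0]),
                        np.array([-10.0, -3.0, 10.0]),
                        np.array([-1.0, -0.3, 1.0]), 10.0)
        curve = ea.conductance_curve(iv, 40.0)
        assert 37.0 not in curve["voltage_mV"].to_numpy()

    def test_noiseless_r219e_half_activation(self):
        # generator/analysis closed loop with Table-like truth (-46.1, 5.8)
        p = es.preset_params("R219E", "IV")
        traces = es.simulate_protocol(p, es.ProtocolSpec.iv(), seed=0)
        result = ea.analyze_iv(traces, capacitance=9.0)
        curve = result["conductance"]
        g_at_half = np.interp(-46.1, curve["voltage_mV"], curve["g_norm"])
        assert g_at_half == pytest.approx(0.5, abs=0.01)


class TestFitBoltzmann:
    def test_exact_recovery_wt_truth(self):
        v = np.arange(-80.0, 20.1, 5.0)
        y = boltzmann_activation(v, -38.4, 5.4)
        fit = ea.fit_boltzmann(v, y, form="activation")
        assert fit.v_half == pytest.approx(-38.4, abs=1e-6)
        assert fit.k == pytest.approx(5.4, abs=1e-6)

    def test_ninety_percent_point(self):
        # V = v_half + k ln 9 -> y = 1/(1 + e^{-ln 9}) = 0.9 exactly
        v90 = -38.4 + 5.4 * math.log(9.0)
        assert v90 == pytest.approx(-26.53, abs=0.01)
        assert boltzmann_activation(np.array(v90), -38.4, 5.4) == \
            pytest.approx(0.9, abs=1e-9)

    def test_half_at_v_half(self):
        fit = ea.fit_boltzmann(np.arange(-80, 20.0, 5.0),
                               boltzmann_activation(np.arange(-80, 20.0, 5.0),
                                                    -38.4, 5.4))
        assert fit.predict(fit.v_half) == pytest.approx(0.5, abs=1e-9)

    def test_availability_form_decreasing(self):
        v = np.arange(-120.0, 10.1, 5.0)
        y = 1.0 / (1.0 + np.exp((v + 86.6) / 5.6))
        fit = ea.fit_boltzmann(v, y, form="availability")
        assert fit.v_half == pytest.approx(-86.6, abs=1e-6)
        assert fit.k == pytest.approx(5.6, abs=1e-6)
        assert fit.k > 0

    def test_low_confidence_flag(self):
        v = np.array([-30.0, -25.0, -20.0, -15.0, -10.0])
        y = boltzmann_activation(v, -38.4, 5.4)  # upper limb only
        fit = ea.fit_boltzmann(v, y)
        assert fit.low_confidence

    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(-40.0, 40.0))
    def test_voltage_shift_equivariance(self, shift):
        v = np.arange(-80.0, 20.1, 5.0)
        y = boltzmann_activation(v, -38.4, 5.4)
        fit = ea.fit_boltzmann(v + shift, y)
        assert fit.v_half == pytest.approx(-38.4 + shift, abs=1e-5)
        assert fit.k == pytest.approx(5.4, abs=1e-5)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_scale_invariance_after_normalization(self, scale):
        v = np.arange(-80.0, 20.1, 5.0)
        y = boltzmann_activation(v, -38.4, 5.4)
        baseline = ea.fit_boltzmann(v, y / y.max())
        scaled = scale * y
        fit = ea.fit_boltzmann(v, scaled / scaled.max())
        assert fit.v_half == pytest.approx(baseline.v_half, abs=1e-6)
        assert fit.k == pytest.approx(baseline.k, abs=1e-6)


class TestFitRecovery:
    def test_exact_recovery(self):
        dt = np.geomspace(1.0, 3000.0, 12)
        y = 1.0 - 0.6 * np.exp(-dt / 24.51) - 0.4 * np.exp(-dt / 241.1)
        fit = ea.fit_recovery(dt, y)
        assert fit.a_fast == pytest.approx(0.6, rel=1e-4)
        assert fit.tau_fast == pytest.approx(24.51, rel=1e-4)
        assert fit.tau_slow == pytest.approx(241.1, rel=1e-4)

    def test_model_limits(self):
        dt = np.geomspace(1.0, 3000.0, 12)
        y = 1.0 - 0.6 * np.exp(-dt / 24.51) - 0.4 * np.exp(-dt / 241.1)
        fit = ea.fit_recovery(dt, y)
        assert fit.predict(0.0) == pytest.approx(0.0, abs=1e-6)
        assert fit.predict(1e5) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_all_recovered(self):
        dt = np.geomspace(1.0, 3000.0, 12)
        fit = ea.fit_recovery(dt, np.ones_like(dt))
        assert fit.single_exponential_warning

    def test_tau_ordering_enforced(self):
        dt = np.geomspace(1.0, 3000.0, 16)
        y = 1.0 - 0.3 * np.exp(-dt / 200.0) - 0.7 * np.exp(-dt / 20.0)
        fit = ea.fit_recovery(dt, y)
        assert fit.tau_fast < fit.tau_slow
        assert fit.tau_fast == pytest.approx(20.0, rel=1e-3)
        assert fit.a_fast == pytest.approx(0.7, rel=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ea.fit_recovery([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])


class TestCompareGroups:
    def test_identical_groups(self):
        r = ea.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_capacitance_summaries(self):
        # (9.2 - 8.6) / sqrt(0.5^2 + 0.8^2) = 0.636 by hand
        r = ea.compare_groups((8.6, 0.5, 32), (9.2, 0.8, 21))
        assert abs(r.t) == pytest.approx(0.64, abs=0.01)
        assert r.p > 0.05  # not significant

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5]
        r1 = ea.compare_groups(a, b)
        r2 = ea.compare_groups(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_sem_definition(self):
        a = [1.0, 2.0, 3.0, 4.0]
        r = ea.compare_groups(a, [1.0, 2.0])
        assert r.sem_a == pytest.approx(np.std(a, ddof=1) / 2.0)

    def test_zero_variance_equal_means(self):
        r = ea.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ea.compare_groups([1.0], [1.0, 2.0])
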