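"""Tests for the Monod update machinery and the firing-block procedure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aglif import (
    MonodCoefficients,
    NondimensionalParameters,
    adjust_monod_out_of_range,
    after_spike_conditions,
    block_cutoff,
    build_block_rule,
    complete_parameters,
    detect_firing_block,
    first_spike_conditions,
    monod_properties,
    monod_value,
    nondimensionalize,
    threshold_H,
)


def nd(alpha=0.2, beta=0.4, delta=0.1):
    return NondimensionalParameters(
        alpha=alpha, beta=beta, delta=delta, tau=10.0,
        Vth_tilde=-0.72, Vr_tilde=-0.85, alpha_th=0.05,
    )


class TestMonodValue:
    def test_value_at_zero_elapsed_is_intercept(self):
        m = MonodCoefficients(a=2.0, b=1e-3, c=0.7, d=30.0)
        assert monod_value(m, 0.0, 600.0) == pytest.approx(0.7)

    def test_plateau_at_large_elapsed(self):
        m = MonodCoefficients(a=2.0, b=1e-3, c=0.7, d=30.0)
        plateau = m.plateau(600.0)
        assert monod_value(m, 1e9, 600.0) == pytest.approx(plateau, rel=1e-6)
        assert plateau == pytest.approx(0.7 + 2.0 * math.exp(0.6))

    def test_halfway_point(self):
        m = MonodCoefficients(a=2.0, b=0.0, c=1.0, d=5.0)
        assert monod_value(m, 5.0, 123.0) == pytest.approx(2.0)

    def test_negative_elapsed_rejected(self):
        m = MonodCoefficients(a=1.0, b=0.0, c=0.0, d=5.0)
        with pytest.raises(ValueError):
            monod_value(m, -1.0, 100.0)


class TestMonodProperties:
    def test_positive_a_nonneg_c_global(self):
        rep = monod_properties(MonodCoefficients(a=1.0, b=0.004, c=0.5, d=10.0))
        assert rep.positivity_verdict == "global"
        assert rep.monotone_in_chi == "increasing"
        assert rep.monotone_in_I == "increasing"

    def test_negative_a_negative_b_large_c_global(self):
        rep = monod_properties(MonodCoefficients(a=-1.0, b=-0.01, c=1.5, d=10.0))
        assert rep.positivity_verdict == "global"
        assert rep.monotone_in_chi == "decreasing"
        assert rep.monotone_in_I == "increasing"

    def test_negative_plateau_fails(self):
        # a < 0 with b > 0: plateau c + a e^{bI} goes negative for large I
        # and c < -a, so neither sufficient nor necessary conditions hold
        m = MonodCoefficients(a=-1.0, b=0.01, c=0.2, d=10.0)
        assert monod_properties(m).positivity_verdict == "fails"
        assert m.plateau(1000.0) < 0

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-2, 2).filter(lambda x: abs(x) > 1e-3),
        b=st.floats(-5e-3, 5e-3),
        c=st.floats(-1, 2),
        d=st.floats(1.0, 100.0),
    )
    def test_monotonicity_matches_finite_differences(self, a, b, c, d):
        m = MonodCoefficients(a=a, b=b, c=c, d=d)
        rep = monod_properties(m)
        chis = np.linspace(0.5, 500.0, 100)
        vals = np.array([monod_value(m, x, 500.0) for x in chis])
        dchi = np.diff(vals)
        assert np.all(dchi >= -1e-12) if rep.monotone_in_chi == "increasing" else np.all(dchi <= 1e-12)
        Is = np.linspace(100.0, 1000.0, 100)
        vals_I = np.array([monod_value(m, 50.0, I) for I in Is])
        dI = np.diff(vals_I)
        if rep.monotone_in_I == "increasing":
            assert np.all(dI >= -1e-12)
        elif rep.monotone_in_I == "decreasing":
            assert np.all(dI <= 1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        a=st.floats(-2, 2).filter(lambda x: abs(x) > 1e-3),
        b=st.floats(-4e-3, 4e-3),
        c=st.floats(-1, 2),
        d=st.floats(1.0, 100.0),
    )
    def test_global_verdict_matches_brute_force_minimum(self, a, b, c, d):
        m = MonodCoefficients(a=a, b=b, c=c, d=d)
        rep = monod_properties(m)
        chis = np.concatenate([np.linspace(1e-3, 100, 60), np.linspace(100, 1e4, 60)])
        Is = np.linspace(1.0, 2000.0, 50)
        grid_min = min(
            monod_value(m, x, I) for x in (chis[0], chis[-1], d) for I in Is
        )
        # the extremes in chi bound the function (monotone in chi)
        if rep.positivity_verdict == "global":
            assert grid_min >= -1e-9


class TestThresholdH:
    def test_rest_state_reduces_to_alpha_over_beta(self):
        n = nd(alpha=0.2, beta=0.4, delta=0.1)
        assert threshold_H(n, 0.0, -1.0) == pytest.approx(0.5)

    def test_strictly_increasing_in_alpha(self):
        n1, n2 = nd(alpha=0.2), nd(alpha=0.3)
        assert threshold_H(n2, 0.1, -0.85) > threshold_H(n1, 0.1, -0.85)

    def test_slope_in_dimensional_current(self, reference_params):
        # dH/dI = 1/(K beta)
        p = reference_params
        n1 = nondimensionalize(p, 400.0)
        n2 = nondimensionalize(p, 500.0)
        dH = threshold_H(n2, 0.0, -1.0) - threshold_H(n1, 0.0, -1.0)
        assert dH == pytest.approx(100.0 / (p.K * n1.beta), rel=1e-12)


class TestAdjustMonod:
    def test_already_positive_returned_unchanged(self):
        m = MonodCoefficients(a=1.0, b=1e-3, c=0.5, d=20.0)
        assert adjust_monod_out_of_range(m, nd(), 600.0) is m

    def test_eta_zero_formula_with_zero_depolarizing(self):
        # with I_dep0 = 0 and V0 = -1 the translated intercept is
        # alpha/beta - a e^{bI} for every eta
        n = nd(alpha=0.2, beta=0.4, delta=0.1)
        m = MonodCoefficients(a=0.3, b=0.0, c=-1.0, d=20.0)
        adj = adjust_monod_out_of_range(m, n, 600.0, I_dep0=0.0, V0=-1.0)
        assert adj.c == pytest.approx(n.alpha / n.beta - 0.3)

    def test_fallback_zeroes_value_at_first_spike(self):
        # at 900 pA the term a e^{bI} dwarfs the translation budget, so no
        # grid value of eta restores positivity and the c - L fallback fires,
        # zeroing the update at the first spike time
        n = nd(alpha=0.01, beta=0.4, delta=0.1)
        m = MonodCoefficients(a=0.5, b=0.01, c=-4000.0, d=20.0)
        chi_first = 15.0
        adj = adjust_monod_out_of_range(m, n, 900.0, chi_first=chi_first)
        assert monod_value(adj, chi_first, 900.0) == pytest.approx(0.0, abs=1e-9)


class TestInitialConditions:
    def test_first_spike_from_rest(self, reference_params):
        p = reference_params
        n = nondimensionalize(p, 0.0)
        ic = first_spike_conditions(p, n, 0.0)
        assert (ic.V0, ic.I_adap0, ic.I_dep0) == (-1.0, 0.0, 0.0)

    def test_subthreshold_current_gives_no_kick(self, reference_params):
        p = reference_params
        ic = first_spike_conditions(p, nondimensionalize(p, p.I_th), p.I_th)
        assert ic.I_dep0 == 0.0

    def test_kick_linear_in_excess_current(self, reference_params):
        p = reference_params
        I = p.I_th + 100.0
        ic = first_spike_conditions(p, nondimensionalize(p, I), I)
        cur = -p.k_2 / (p.E_L * p.k_adap)
        assert ic.I_dep0 == pytest.approx(p.I_dep_start * 100.0 * cur)

    def test_after_spike_limit_is_intercept(self, reference_params):
        p = reference_params
        n = nondimensionalize(p, 600.0)
        m = MonodCoefficients(a=1.0, b=1e-3, c=0.4, d=30.0)
        ic = after_spike_conditions(p, n, m, t_spk_plus_ms=1e-9, t_start_ms=0.0, I_stim=600.0)
        assert ic.I_adap0 == pytest.approx(m.c, abs=1e-9)
        assert ic.V0 == pytest.approx(n.Vr_tilde)

    def test_after_spike_updates_nondecreasing_for_adapting(self, reference_params):
        p = reference_params
        n = nondimensionalize(p, 600.0)
        m = MonodCoefficients(a=1.0, b=1e-3, c=0.4, d=30.0)
        vals = [
            after_spike_conditions(p, n, m, t, 0.0, 600.0).I_adap0
            for t in (10.0, 30.0, 80.0, 200.0)
        ]
        assert vals == sorted(vals)

    def test_negative_update_clipped_to_zero(self, reference_params):
        p = reference_params
        n = nondimensionalize(p, 600.0)
        m = MonodCoefficients(a=-0.5, b=-1e-3, c=0.05, d=10.0)
        ic = after_spike_conditions(p, n, m, 300.0, 0.0, 600.0)
        assert ic.I_adap0 == 0.0

    def test_h_flag_raised_above_bound(self, reference_params):
        p = reference_params
        n = nondimensionalize(p, 600.0)
        cur = -p.k_2 / (p.E_L * p.k_adap)
        H = threshold_H(n, p.I_dep0 * cur, n.Vr_tilde)
        m = MonodCoefficients(a=0.0, b=0.0, c=2.0 * H + 1.0, d=1.0)
        ic = after_spike_conditions(p, n, m, 100.0, 0.0, 600.0)
        assert ic.H_exceeded


class TestDetectFiringBlock:
    def test_early_silence_is_block(self):
        blocked, never = detect_firing_block([260.0, 300.0], 400.0)
        assert blocked and not never

    def test_late_last_spike_is_not_block(self):
        blocked, never = detect_firing_block([320.0, 350.0], 400.0)
        assert not blocked

    def test_single_spike_never_blocked(self):
        assert detect_firing_block([100.0], 400.0) == (False, False)

    def test_empty_train_never_fired(self):
        assert detect_firing_block([], 400.0) == (False, True)


class TestBlockRule:
    def test_two_interval_lines_and_thresholds(self, blocking_raster_two_intervals):
        rule = build_block_rule(blocking_raster_two_intervals, 400.0)
        assert len(rule.lines) == 2
        lo, hi = rule.lines
        assert round(lo.A_coef, 2) == 0.68
        assert lo.B_coef == pytest.approx(123.80, abs=1e-9)
        assert lo.threshold == 300.0 and lo.side == "le"
        assert round(hi.A_coef, 2) == -0.17
        assert hi.B_coef == pytest.approx(378.35, abs=1e-9)
        assert hi.threshold == 500.0 and hi.side == "ge"
        assert rule.I_fire == (400.0, 400.0)

    def test_single_interval_line_and_threshold(self, blocking_raster_single_interval):
        rule = build_block_rule(blocking_raster_single_interval, 400.0)
        assert len(rule.lines) == 1
        (ln,) = rule.lines
        assert round(ln.A_coef, 2) == 0.47
        assert ln.B_coef == pytest.approx(31.20, abs=1e-9)
        assert ln.threshold == 700.0 and ln.side == "le"
        assert rule.block_intervals == ((400.0, 600.0),)
        assert rule.I_fire == (800.0,)

    def test_lines_pass_through_anchor_points(self, blocking_raster_two_intervals):
        rule = build_block_rule(blocking_raster_two_intervals, 400.0)
        for ln in rule.lines:
            for I, t in (ln.P1, ln.P2):
                assert ln.cutoff(I) == pytest.approx(t, abs=1e-9)

    def test_cutoff_uses_exact_unrounded_line(self, blocking_raster_two_intervals):
        rule = build_block_rule(blocking_raster_two_intervals, 400.0)
        assert block_cutoff(rule, 250.0) == pytest.approx(0.68075 * 250.0 + 123.80)

    def test_gap_current_keeps_firing(self, blocking_raster_two_intervals):
        rule = build_block_rule(blocking_raster_two_intervals, 400.0)
        assert block_cutoff(rule, 400.0) is None

    def test_extrapolated_high_current_is_cut(self, blocking_raster_two_intervals):
        rule = build_block_rule(blocking_raster_two_intervals, 400.0)
        assert block_cutoff(rule, 900.0) is not None

    def test_no_blocking_currents_gives_empty_rule(self, blocking_raster_two_intervals):
        from aglif import SpikeRaster

        raster = SpikeRaster(trains={400.0: np.array([100.0, 200.0, 390.0])}, T=400.0)
        rule = build_block_rule(raster, 400.0)
        assert rule.lines == ()
        assert block_cutoff(rule, 400.0) is None

    def test_error_without_firing_reference(self):
        from aglif import SpikeRaster

        raster = SpikeRaster(
            trains={400.0: np.array([50.0, 80.0]), 600.0: np.array([])}, T=400.0
        )
        with pytest.raises(ValueError):
            build_block_rule(raster, 400.0)
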