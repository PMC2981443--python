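"""Glide polar optima, stall/span behaviour and burst performance."""

import math

import numpy as np
import pytest

from pterosoar.flight_performance import (
    BurstModel,
    GlidePolarParams,
    InsufficientPowerError,
    Planform,
    anaerobic_power,
    best_glide_speed,
    body_frontal_area,
    burst_range,
    burst_speed,
    drag_coefficients,
    effective_span_fraction,
    flapping_frequency,
    glide_drag,
    glide_performance,
    minimum_sink_speed,
    stall_speed,
)


class TestBodyArea:
    def test_unit_mass(self):
        assert body_frontal_area(1.0) == pytest.approx(0.00813)

    def test_seventy_kg(self):
        assert body_frontal_area(70.0) == pytest.approx(0.1376, rel=1e-3)

    def test_zero_exponent_constant(self):
        p = GlidePolarParams(body_area_exp=0.0)
        assert body_frontal_area(1.0, p) == body_frontal_area(300.0, p)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            body_frontal_area(0.0)


class TestDragPolar:
    def test_two_term_identity(self, chatterjee_planform, default_params):
        """D(V) is exactly A V^2 + B / V^2 for the decomposed coefficients."""
        A, B = drag_coefficients(chatterjee_planform, default_params)
        for v in (5.0, 13.0, 40.0):
            assert glide_drag(v, chatterjee_planform, default_params) == pytest.approx(
                A * v**2 + B / v**2
            )

    def test_drag_diverges_at_both_ends(self, chatterjee_planform):
        mid = glide_drag(13.0, chatterjee_planform)
        assert glide_drag(0.5, chatterjee_planform) > 50 * mid
        assert glide_drag(500.0, chatterjee_planform) > 50 * mid

    def test_nonpositive_speed_rejected(self, chatterjee_planform):
        with pytest.raises(ValueError):
            glide_drag(0.0, chatterjee_planform)

    def test_closed_form_optima_match_grid_search(self, random_planforms):
        """Analytic best-glide and min-sink equal a 1000-point grid search."""
        params = GlidePolarParams()
        for pf in random_planforms:
            vs = stall_speed(pf, params)
            grid = np.geomspace(vs * 0.5, max(60.0, vs * 6), 1000)
            drags = np.array([glide_drag(v, pf, params) for v in grid])
            sinks = drags * grid / pf.weight()
            v_bg = best_glide_speed(pf, params)
            v_ms, sink = minimum_sink_speed(pf, params)
            # optimum value within 0.1% of grid minimum
            assert glide_drag(v_bg, pf, params) <= drags.min() * 1.001
            assert sink <= sinks.min() * 1.001
            # optimum location within one grid step
            step = math.log(grid[1] / grid[0])
            assert abs(math.log(v_bg / grid[np.argmin(drags)])) <= 1.5 * step
            assert abs(math.log(v_ms / grid[np.argmin(sinks)])) <= 1.5 * step


class TestCharacteristicSpeeds:
    def test_quarter_power_weight_scaling(self, default_params):
        """Quadrupling weight doubles best glide speed when Sb is held fixed."""
        p = GlidePolarParams(body_area_exp=0.0)  # freeze Sb against mass
        base = Planform(span=10.0, area=10.0, mass=50.0)
        heavy = Planform(span=10.0, area=10.0, mass=200.0)
        assert best_glide_speed(heavy, p) == pytest.approx(
            2 * best_glide_speed(base, p), rel=1e-9
        )

    def test_bg_over_ms_is_fourth_root_of_three(self, random_planforms):
        for pf in random_planforms[:20]:
            v_bg = best_glide_speed(pf)
            v_ms, _ = minimum_sink_speed(pf)
            assert v_bg / v_ms == pytest.approx(3**0.25, rel=1e-9)

    def test_speed_ordering_on_every_planform(self, random_planforms):
        """stall(2.2) < stall(1.8) < min sink < best glide."""
        params = GlidePolarParams()
        for pf in random_planforms:
            v_unsteady = stall_speed(pf, params, params.cl_max_unsteady)
            v_steady = stall_speed(pf, params, params.cl_max_steady)
            v_ms, _ = minimum_sink_speed(pf, params)
            v_bg = best_glide_speed(pf, params)
            assert v_unsteady < v_steady < v_ms < v_bg

    def test_chatterjee_stall_speed(self, chatterjee_planform):
        assert stall_speed(chatterjee_planform, cl=2.2) == pytest.approx(7.29, abs=0.01)

    def test_stall_scales_with_cl(self, chatterjee_planform):
        v1 = stall_speed(chatterjee_planform, cl=2.0)
        v2 = stall_speed(chatterjee_planform, cl=1.0)
        assert v2 == pytest.approx(v1 * math.sqrt(2))

    def test_wing_loading_monotonicity(self):
        """At fixed aspect ratio, faster best glide with higher wing loading."""
        p = GlidePolarParams()
        speeds = []
        for loading in (50.0, 100.0, 200.0, 400.0):
            mass = 100.0
            area = mass * p.g / loading
            span = math.sqrt(8.0 * area)
            speeds.append(best_glide_speed(Planform(span=span, area=area, mass=mass), p))
        assert all(a < b for a, b in zip(speeds, speeds[1:]))

    def test_glide_ratio_weight_independent_with_fixed_body(self):
        p = GlidePolarParams(body_area_exp=0.0)
        r = []
        for mass in (50.0, 100.0, 200.0):
            pf = Planform(span=10.0, area=10.0, mass=mass)
            r.append(glide_performance(pf, p).best_glide_ratio)
        assert max(r) == pytest.approx(min(r), rel=1e-9)


class TestSpanReduction:
    def test_endpoints_and_clamp(self, chatterjee_planform):
        vs = stall_speed(chatterjee_planform)
        assert effective_span_fraction(vs, chatterjee_planform) == pytest.approx(1.0)
        assert effective_span_fraction(2 * vs, chatterjee_planform) == pytest.approx(0.8)
        assert effective_span_fraction(10 * vs, chatterjee_planform) == pytest.approx(0.8)

    def test_linear_midpoint(self, chatterjee_planform):
        vs = stall_speed(chatterjee_planform)
        assert effective_span_fraction(1.5 * vs, chatterjee_planform) == pytest.approx(0.9)

    def test_below_stall_rejected(self, chatterjee_planform):
        vs = stall_speed(chatterjee_planform)
        with pytest.raises(ValueError):
            effective_span_fraction(0.9 * vs, chatterjee_planform)


class TestFlappingFrequency:
    def test_wandering_albatross(self):
        assert flapping_frequency(8.73, 3.03, 0.61) == pytest.approx(2.66, abs=0.01)

    def test_three_eighths_mass_power(self):
        f1 = flapping_frequency(10.0, 3.0, 0.6)
        f2 = flapping_frequency(20.0, 3.0, 0.6)
        assert f2 / f1 == pytest.approx(2 ** (3.0 / 8.0))

    def test_geometric_similarity_gives_minus_one_sixth(self):
        """b ~ M^(1/3), S ~ M^(2/3) collapses the law to f ~ M^(-1/6)."""
        f = []
        for M in (8.0, 64.0):
            b = M ** (1 / 3)
            S = M ** (2 / 3) / 10
            f.append(flapping_frequency(M, b, S))
        assert f[1] / f[0] == pytest.approx(8 ** (-1.0 / 6.0), rel=1e-9)


class TestBurst:
    def test_anaerobic_power_arithmetic(self):
        burst = BurstModel(muscle_fraction=0.25, specific_power=400.0)
        assert anaerobic_power(200.0, burst) == pytest.approx(20000.0)
        assert anaerobic_power(200.0, BurstModel(muscle_fraction=0.0)) == 0.0

    def test_burst_range_examples(self):
        one_minute = BurstModel(burst_duration=60.0)
        assert burst_range(48.3, one_minute) == pytest.approx(2898.0)
        assert burst_range(10.0, one_minute) == pytest.approx(600.0)
        assert burst_range(48.3, BurstModel(burst_duration=0.0)) == 0.0

    def test_insufficient_power_signalled(self, witton_planform):
        with pytest.raises(InsufficientPowerError):
            burst_speed(witton_planform, power=10.0, climb_rate=1.0)

    def test_tangency_power_gives_cheapest_speed(self, chatterjee_planform):
        params = GlidePolarParams()
        pf = chatterjee_planform
        v_ms, _ = minimum_sink_speed(pf, params)
        p_min = glide_drag(v_ms, pf, params) * v_ms + pf.weight() * 1.0
        v = burst_speed(pf, params, power=p_min * 1.000001, climb_rate=1.0)
        assert v == pytest.approx(v_ms, rel=0.01)

    def test_larger_root_matches_dense_grid(self, chatterjee_planform):
        """Power 1% above minimum: two roots, the larger one is returned."""
        params = GlidePolarParams()
        pf = chatterjee_planform
        v_ms, _ = minimum_sink_speed(pf, params)
        p_min = glide_drag(v_ms, pf, params) * v_ms + pf.weight() * 1.0
        power = 1.01 * p_min
        v = burst_speed(pf, params, power=power, climb_rate=1.0)
        grid = np.linspace(stall_speed(pf, params), 100.0, 200_000)
        demand = np.array([glide_drag(x, pf, params) * x for x in grid])
        feasible = grid[demand + pf.weight() * 1.0 <= power]
        assert v == pytest.approx(feasible.max(), rel=1e-3)
        assert v > v_ms  # the larger of the two roots

    def test_monotone_in_power_and_climb(self, witton_planform):
        params = GlidePolarParams()
        p0 = anaerobic_power(witton_planform.mass, BurstModel())
        speeds = [
            burst_speed(witton_planform, params, power=p, climb_rate=1.0)
            for p in (p0, 1.5 * p0, 3.0 * p0)
        ]
        assert speeds[0] < speeds[1] < speeds[2]
        fast_climb = burst_speed(witton_planform, params, power=p0, climb_rate=3.0)
        assert fast_climb <= speeds[0]


def test_performance_summary_consistency(witton_planform):
    perf = glide_performance(witton_planform)
    assert perf.v_stall < perf.v_min_sink < perf.v_best_glide
    assert perf.min_sink_rate > 0
    assert perf.best_glide_ratio > 1
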