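"""Pendulum drift, closed-form depth bounds, and the step-by-step oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stairsafe import (
    ModelParams,
    StaircaseSpec,
    audit_staircase,
    delta_com,
    sdp_lower_bound,
    sdp_range,
    sdp_upper_bound,
    simulate_descent,
)
from stairsafe.stability import study_sites


def closed_form_risky(pfc, eta, dcom, d, n):
    """Independent oracle: depth below the worst-case minimum over k <= n."""
    return any(pfc + eta + (k - 1) * dcom > k * d for k in range(1, n + 1))


class TestDeltaCom:
    def test_stationary_pendulum_has_no_drift(self):
        assert delta_com(0.0, 0.81) == 0.0

    def test_reference_value(self):
        # 0.88 * sqrt(0.81 / 9.81), frozen from direct evaluation
        assert delta_com(0.88, 0.81, 9.81) == pytest.approx(0.2528661, abs=1e-6)

    @given(st.floats(0.01, 3), st.floats(0.3, 1.2))
    def test_equals_v_over_eigenfrequency(self, v, l):
        omega0 = math.sqrt(9.81 / l)
        assert delta_com(v, l) == pytest.approx(v / omega0, rel=1e-12)

    @given(st.floats(0.01, 2), st.floats(0.3, 1.2))
    def test_linear_in_speed(self, v, l):
        assert delta_com(2 * v, l) == pytest.approx(2 * delta_com(v, l), rel=1e-12)

    @pytest.mark.parametrize("l,g", [(0.0, 9.81), (-1, 9.81), (0.8, 0.0)])
    def test_rejects_nonpositive_length_or_gravity(self, l, g):
        with pytest.raises(ValueError):
            delta_com(0.9, l, g)


class TestBounds:
    def test_single_step_lower_bound_is_foot_geometry(self):
        assert sdp_lower_bound(0.08, 0.11, 0.0, 1) == pytest.approx(0.19)

    def test_lower_bound_at_reference_means(self):
        dcom = delta_com(0.88, 0.81)
        # (0.19 + 11 * 0.2528661) / 12, frozen from direct evaluation
        assert sdp_lower_bound(0.08, 0.11, dcom, 12) == pytest.approx(0.2476273, abs=1e-6)

    def test_lower_bound_increases_with_n_when_drift_dominates(self):
        dcom = 0.25
        vals = [sdp_lower_bound(0.08, 0.11, dcom, n) for n in range(2, 21)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_upper_bound_at_reference_means(self):
        dcom = delta_com(0.88, 0.81)
        # (0.304 + 12 * 0.2528661) / 11, frozen from direct evaluation
        assert sdp_upper_bound(0.08, 0.224, dcom, 12) == pytest.approx(0.3034903, abs=1e-6)

    def test_upper_bound_without_drift_reduces_to_reach(self):
        assert sdp_upper_bound(0.08, 0.224, 0.0, 2) == pytest.approx(0.304)

    def test_upper_bound_decreasing_in_n(self):
        dcom = delta_com(0.88, 0.81)
        vals = [sdp_upper_bound(0.08, 0.224, dcom, n) for n in range(2, 21)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_tread_rule_reproduces_published_upper_columns(self):
        """The published table's upper-bound values follow the /N arithmetic."""
        dcom = delta_com(0.88, 0.81)
        assert round(sdp_upper_bound(0.08, 0.224, dcom, 7, rule="tread"), 3) == 0.296
        assert round(sdp_upper_bound(0.08, 0.224, delta_com(0.8612009, 0.81), 7,
                                     rule="tread"), 3) == 0.291
        assert round(sdp_upper_bound(0.08, 0.224, delta_com(0.8987991, 0.81), 7,
                                     rule="tread"), 3) == 0.302

    @pytest.mark.parametrize("n,err", [(0, True), (1, False)])
    def test_lower_bound_n_domain(self, n, err):
        if err:
            with pytest.raises(ValueError):
                sdp_lower_bound(0.1, 0.1, 0.2, n)
        else:
            sdp_lower_bound(0.1, 0.1, 0.2, n)

    def test_upper_bound_requires_two_steps(self):
        with pytest.raises(ValueError):
            sdp_upper_bound(0.08, 0.224, 0.25, 1)


class TestRange:
    def test_reference_range(self, reference_params):
        lo, hi = sdp_range(reference_params, 12)
        assert lo == pytest.approx(0.2476273, abs=1e-6)
        assert hi == pytest.approx(0.3034903, abs=1e-6)

    def test_zero_speed_two_steps(self):
        params = ModelParams(v=0.0, l=0.81, L=0.224, eta=0.11, pfc=0.08)
        lo, hi = sdp_range(params, 2)
        assert (lo, hi) == pytest.approx((0.095, 0.304))

    @given(st.floats(0.3, 1.2), st.floats(0.5, 1.0), st.integers(2, 15))
    def test_feasibility_contract(self, v, l, n):
        params = ModelParams(v=v, l=l, L=0.224, eta=0.11, pfc=0.08)
        lo, hi = sdp_range(params, n)
        assert lo < hi

    @given(st.floats(0.5, 2.0), st.floats(0.3, 1.2), st.floats(0.4, 1.1),
           st.integers(2, 15))
    def test_dimensional_scaling(self, c, v, l, n):
        """Scaling all lengths by c and v by sqrt(c) scales both bounds by c."""
        p1 = ModelParams(v=v, l=l, L=0.224, eta=0.11, pfc=0.08)
        p2 = ModelParams(v=v * math.sqrt(c), l=l * c, L=0.224 * c,
                         eta=0.11 * c, pfc=0.08 * c)
        lo1, hi1 = sdp_range(p1, n)
        lo2, hi2 = sdp_range(p2, n)
        assert lo2 == pytest.approx(c * lo1, rel=1e-9)
        assert hi2 == pytest.approx(c * hi1, rel=1e-9)


class TestSimulator:
    def _staircase(self, d, n=12):
        return StaircaseSpec(name="t", riser_height=0.15, step_depth=d,
                             step_width=1.4, n_steps=n)

    def test_depth_inside_range_never_flags(self, reference_params):
        lo, hi = sdp_range(reference_params, 12)
        states = simulate_descent(reference_params, self._staircase((lo + hi) / 2))
        assert not any(s.risky or s.over_reach for s in states)

    def test_depth_below_lower_bound_flags_risk(self, reference_params):
        lo, _ = sdp_range(reference_params, 12)
        states = simulate_descent(reference_params, self._staircase(lo - 0.01))
        assert any(s.risky for s in states)

    def test_no_drift_no_flags(self):
        params = ModelParams(v=0.0, l=0.81, L=0.224, eta=0.11, pfc=0.08)
        states = simulate_descent(params, self._staircase(0.25))
        assert not any(s.risky for s in states)

    def test_margin_matches_edge_minus_cop(self, reference_params):
        for s in simulate_descent(reference_params, self._staircase(0.28)):
            assert s.margin == pytest.approx(s.bos_edge - s.cop_position)

    def test_matches_independent_closed_form(self, rng):
        """Simulator risk flag iff depth violates the worst-case lower bound."""
        for _ in range(500):
            pfc, eta = rng.uniform(0.0, 0.15), rng.uniform(0.02, 0.15)
            v, l = rng.uniform(0.1, 1.6), rng.uniform(0.4, 1.1)
            d, n = rng.uniform(0.1, 0.45), int(rng.integers(2, 16))
            params = ModelParams(v=v, l=l, L=max(eta + 0.05, 0.2), eta=eta, pfc=pfc)
            st_ = StaircaseSpec(name="g", riser_height=0.15, step_depth=d,
                                step_width=1.4, n_steps=n)
            flagged = any(s.risky for s in simulate_descent(params, st_))
            assert flagged == closed_form_risky(pfc, eta, params.delta_com, d, n)


class TestAudit:
    def test_chengguan_site_is_safe_at_reference_means(self, reference_params, sites):
        audit = audit_staircase(sites["chengguan"], reference_params,
                                n_range=range(7, 13))
        assert audit.safe
        assert audit.d_low < 0.28 < audit.d_high

    def test_shallow_tread_is_unsafe_with_named_violation(self, reference_params):
        st_ = StaircaseSpec(name="shallow", riser_height=0.15, step_depth=0.10,
                            step_width=1.4, n_steps=12)
        audit = audit_staircase(st_, reference_params, n_range=range(7, 13))
        assert not audit.safe
        assert any("minimum" in v or "<" in v for v in audit.violations)

    def test_single_n_reduces_to_sdp_range(self, reference_params, sites):
        audit = audit_staircase(sites["gugua"], reference_params, n_range=[2])
        lo, hi = sdp_range(reference_params, 2)
        assert (audit.d_low, audit.d_high) == pytest.approx((lo, hi))

    def test_empty_n_range_rejected(self, reference_params, sites):
        with pytest.raises(ValueError):
            audit_staircase(sites["gugua"], reference_params, n_range=[])


class TestStaircaseSpec:
    def test_incline_computed_from_geometry(self):
        s = StaircaseSpec(name="x", riser_height=0.15, step_depth=0.30,
                          step_width=1.6, n_steps=12)
        assert s.incline_deg == pytest.approx(26.565, abs=0.01)

    def test_inconsistent_declared_incline_rejected(self):
        with pytest.raises(ValueError):
            StaircaseSpec(name="x", riser_height=0.15, step_depth=0.30,
                          step_width=1.6, n_steps=12, incline_deg=30.0)

    def test_csv_round_trip(self, sites, tmp_path):
        from stairsafe.stability import read_staircases_csv, write_staircases_csv

        path = tmp_path / "stairs.csv"
        specs = list(sites.values())
        write_staircases_csv(specs, path)
        assert read_staircases_csv(path) == specs
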