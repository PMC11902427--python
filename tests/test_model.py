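"""Torque-law unit and property tests: passive spline, active hinge, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgabs.model import (
    ActiveRow,
    AssistanceConfig,
    InputError,
    PassiveKeypointTable,
    ValidationError,
    active_torque,
    passive_torque,
    scale_active_percentages,
    scale_passive_percentages,
    total_torque,
)

PCTS = list(range(0, 101, 10))


@pytest.fixture
def passive_table(truth_spec):
    return truth_spec.passive_table


@pytest.fixture
def active_table(truth_spec):
    return truth_spec.active_table


class TestPassiveTorque:
    def test_zero_at_first_angle_when_anchored(self, passive_table):
        assert passive_torque(passive_table.characteristic_angles[0], passive_table, 100) == 0.0

    @pytest.mark.parametrize("eta_p", [40, 70, 100])
    def test_interpolant_passes_through_knots(self, passive_table, eta_p):
        tau_max = passive_table.max_torque(eta_p)
        for ang, ratio in zip(passive_table.characteristic_angles, passive_table.torque_ratios):
            expected = ratio * tau_max
            got = passive_torque(ang, passive_table, eta_p)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_zero_percentage_gives_zero_everywhere(self, passive_table):
        theta = np.linspace(-10, 120, 50)
        assert np.all(passive_torque(theta, passive_table, 0) == 0.0)

    def test_monotone_between_monotone_knots(self, passive_table):
        # shape-preserving sections: monotone keypoints imply monotone curve
        theta = np.linspace(0, 80, 1000)
        tau = passive_torque(theta, passive_table, 100)
        assert np.all(np.diff(tau) >= -1e-12)

    def test_clamped_outside_knot_range(self, passive_table):
        tau_max = passive_table.max_torque(100)
        assert passive_torque(200.0, passive_table, 100) == pytest.approx(tau_max)
        assert passive_torque(-15.0, passive_table, 100) == 0.0

    def test_rejects_non_decade_percentage(self, passive_table):
        with pytest.raises(InputError):
            passive_torque(30.0, passive_table, 55)

    def test_table_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PassiveKeypointTable((0, 10, 20, 30, 25), (0, 0.2, 0.5, 0.8, 1.0), {100: 10.0})
        with pytest.raises(ValidationError):
            PassiveKeypointTable((0, 10, 20, 30, 40), (0, 0.5, 0.2, 0.8, 1.0), {100: 10.0})
        with pytest.raises(ValidationError):
            PassiveKeypointTable((0, 10, 20, 30, 40), (0, 0.2, 0.5, 0.8, 0.9), {100: 10.0})


class TestActiveTorque:
    def test_zero_below_threshold(self, active_table):
        row = active_table.row(100)
        assert active_torque(row.vel_lim / 2.0, active_table, 100) == 0.0

    def test_saturates_above_vel_max(self, active_table):
        row = active_table.row(100)
        assert active_torque(2.0 * row.vel_max, active_table, 100) == pytest.approx(
            row.tau_a_max
        )

    def test_midpoint_of_linear_section(self, active_table):
        row = active_table.row(100)
        mid = (row.vel_lim + row.vel_max) / 2.0
        assert active_torque(mid, active_table, 100) == pytest.approx(row.tau_a_max / 2.0)

    def test_negative_speed_rejected(self, active_table):
        with pytest.raises(InputError):
            active_torque(-1.0, active_table, 100)

    @pytest.mark.parametrize("eta_a", PCTS)
    def test_hinge_contract_on_dense_grid(self, active_table, eta_a):
        """Zero below vel_lim, affine between, constant above, continuous at both."""
        row = active_table.row(eta_a)
        speed = np.linspace(0, 2 * max(row.vel_max, 1.0), 2000)
        tau = active_torque(speed, active_table, eta_a)
        if row.tau_a_max == 0:
            assert np.all(tau == 0)
            return
        below = speed < row.vel_lim
        between = (speed >= row.vel_lim) & (speed <= row.vel_max)
        above = speed > row.vel_max
        assert np.all(tau[below] == 0)
        assert np.allclose(
            tau[between], row.slope * speed[between] + row.intercept, atol=1e-9
        )
        assert np.all(tau[above] == row.tau_a_max)
        assert abs(active_torque(row.vel_lim, active_table, eta_a)) < 1e-9
        assert abs(active_torque(row.vel_max, active_table, eta_a) - row.tau_a_max) < 1e-9

    def test_row_line_through_threshold(self):
        with pytest.raises(ValidationError):
            ActiveRow(tau_a_max=10.0, vel_lim=5.0, slope=1.0, intercept=3.0)


class TestTotalTorque:
    def test_all_off_is_zero(self, truth_spec):
        from dataclasses import replace

        spec = replace(truth_spec, assistance=AssistanceConfig(0, 0, 20.0))
        assert total_torque(45.0, 50.0, False, spec) == 0.0

    def test_additivity_at_saturation(self, truth_spec):
        row = truth_spec.active_table.row(100)
        tau_p = passive_torque(45.0, truth_spec.passive_table, 100)
        got = total_torque(45.0, 2 * row.vel_max, True, truth_spec)
        assert got == pytest.approx(tau_p + row.tau_a_max)

    def test_hybrid_sweep_equals_independent_sum(self, truth_spec):
        speeds = np.linspace(0, 80, 400)
        combined = total_torque(50.0, speeds, True, truth_spec)
        separate = passive_torque(50.0, truth_spec.passive_table, 100) + active_torque(
            speeds, truth_spec.active_table, 100
        )
        assert np.allclose(combined, separate, atol=1e-12)

    def test_gate_disables_active_only(self, truth_spec):
        tau_p = passive_torque(50.0, truth_spec.passive_table, 100)
        assert total_torque(50.0, 60.0, False, truth_spec) == pytest.approx(tau_p)


class TestPercentageScaling:
    def test_even_distribution_between_anchors(self):
        full = scale_passive_percentages({100: 30.0, 70: 24.0})
        assert full[90] == pytest.approx(28.0)
        assert full[80] == pytest.approx(26.0)

    def test_even_distribution_down_to_zero(self):
        full = scale_passive_percentages({40: 12.0})
        assert full[20] == pytest.approx(6.0)
        assert full[0] == 0.0

    def test_anchors_reproduced_bit_exactly(self):
        anchors = {100: 30.0, 70: 24.0, 40: 12.0}
        full = scale_passive_percentages(anchors)
        for pct, tau in anchors.items():
            assert full[pct] == tau  # bit-for-bit

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValidationError):
            scale_passive_percentages({100: 10.0, 70: 24.0})

    def test_active_even_distribution(self):
        table = scale_active_percentages({100: (20.0, 10.0, 40.0), 40: (8.0, 16.0, 52.0)})
        row = table.row(70)
        assert row.tau_a_max == pytest.approx(14.0)
        assert row.vel_lim == pytest.approx(13.0)

    def test_active_intercept_relation(self):
        table = scale_active_percentages({100: (20.0, 15.0, 45.0), 40: (8.0, 22.0, 55.0)})
        for eta in PCTS[1:]:
            row = table.row(eta)
            assert row.intercept == pytest.approx(-row.slope * row.vel_lim, abs=1e-12)
            assert row.vel_max > row.vel_lim

    def test_active_anchors_reproduced(self):
        anchors = {100: (20.0, 15.0, 45.0), 40: (8.0, 22.0, 55.0)}
        table = scale_active_percentages(anchors)
        for pct, (tau, vlim, vmax) in anchors.items():
            row = table.row(pct)
            assert row.tau_a_max == tau and row.vel_lim == vlim
            assert row.vel_max == pytest.approx(vmax)

    def test_degenerate_row_rejected(self):
        with pytest.raises(ValidationError):
            scale_active_percentages({100: (20.0, 40.0, 40.0)})

    @settings(derandomize=True, max_examples=50)
    @given(
        taus=st.lists(
            st.floats(min_value=0.5, max_value=60.0, allow_nan=False), min_size=2, max_size=3
        )
    )
    def test_percentage_monotonicity(self, taus):
        """Max torque is non-decreasing in the percentage for any valid anchors."""
        taus = sorted(taus)
        anchors = dict(zip([40, 70, 100][: len(taus)], taus))
        full = scale_passive_percentages(anchors)
        vals = [full[p] for p in PCTS]
        assert all(b - a >= -1e-12 for a, b in zip(vals, vals[1:]))
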