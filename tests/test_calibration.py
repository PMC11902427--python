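"""Curve averaging, keypoint extraction and the calibration round trip."""

import numpy as np
import pytest
from dataclasses import replace

from conftest import group_by_percentage
from lgabs import simulate_capture
from lgabs.calibration import (
    CalibrationError,
    build_spec,
    calibrate,
    extract_active_anchor,
    extract_passive_anchor,
    normalize_and_average,
)
from lgabs.model import InputError, ValidationError
from lgabs.statics import G


def hinge_curve(tau_a_max=20.0, vel_lim=15.0, vel_max=45.0, d_tt=0.45, n=300, hi=85.0):
    x = np.linspace(1.0, hi, n)
    slope = tau_a_max / (vel_max - vel_lim)
    tau = np.clip(slope * (x - vel_lim), 0.0, tau_a_max)
    force = tau * 2.0 / d_tt / G
    return normalize_and_average([(x, force)], grid_size=n)


class TestNormalizeAndAverage:
    def test_single_trace_preserved(self):
        x = np.linspace(0, 10, 200)
        y = np.sin(x / 3.0)
        curve = normalize_and_average([(x, y)], grid_size=100)
        assert np.max(np.abs(curve.ordinate - np.sin(curve.abscissa / 3.0))) < 1e-3
        assert curve.n_source_curves == 1

    def test_identical_traces_zero_dispersion(self):
        x = np.linspace(0, 5, 100)
        y = x**2
        curve = normalize_and_average([(x, y), (x, y)], grid_size=50)
        assert np.allclose(curve.dispersion, 0.0)

    def test_offset_traces_average_to_midline(self):
        # linearity of the mean: averaging f and f+2 gives f's resample + 1
        x = np.linspace(0, 5, 100)
        y = np.cos(x)
        curve = normalize_and_average([(x, y), (x, y + 2.0)], grid_size=50)
        single = normalize_and_average([(x, y)], grid_size=50)
        assert np.max(np.abs(curve.ordinate - (single.ordinate + 1.0))) < 1e-12
        assert np.max(np.abs(curve.ordinate - (np.cos(curve.abscissa) + 1.0))) < 1e-5

    def test_disjoint_ranges_rejected(self):
        a = (np.linspace(0, 1, 30), np.zeros(30))
        b = (np.linspace(2, 3, 30), np.zeros(30))
        with pytest.raises(InputError):
            normalize_and_average([a, b])

    def test_cubic_section_reproduced_exactly(self):
        # local cubic least squares is exact on polynomial traces
        x = np.linspace(0, 10, 400)
        y = 0.5 * x**3 - x**2 + 2 * x + 1
        curve = normalize_and_average([(x, y)], grid_size=120)
        truth = 0.5 * curve.abscissa**3 - curve.abscissa**2 + 2 * curve.abscissa + 1
        assert np.max(np.abs(curve.ordinate - truth)) < 1e-8


class TestExtractPassiveAnchor:
    def test_round_trip_through_forward_model(self, truth_spec):
        from lgabs.model import passive_torque

        d_tt = truth_spec.body.d_tt
        theta = np.linspace(0, 90, 2000)
        tau = passive_torque(theta, truth_spec.passive_table, 100)
        force = tau * 2.0 / d_tt / G
        curve = normalize_and_average([(theta, force)], grid_size=400)
        tau_max, ratios = extract_passive_anchor(
            curve, truth_spec.passive_table.characteristic_angles, d_tt
        )
        assert tau_max == pytest.approx(truth_spec.passive_table.max_torque(100), rel=1e-6)
        assert np.allclose(ratios, truth_spec.passive_table.torque_ratios, atol=1e-6)

    def test_scaling_curve_scales_tau_max_not_ratios(self, truth_spec):
        from lgabs.model import passive_torque

        d_tt = truth_spec.body.d_tt
        theta = np.linspace(0, 90, 2000)
        force = (
            passive_torque(theta, truth_spec.passive_table, 100) * 2.0 / d_tt / G
        )
        angles = truth_spec.passive_table.characteristic_angles
        c1 = normalize_and_average([(theta, force)], grid_size=400)
        c2 = normalize_and_average([(theta, 2.0 * force)], grid_size=400)
        tau1, r1 = extract_passive_anchor(c1, angles, d_tt)
        tau2, r2 = extract_passive_anchor(c2, angles, d_tt)
        assert tau2 == pytest.approx(2.0 * tau1, rel=1e-9)
        assert np.allclose(r1, r2, atol=1e-9)

    def test_flat_zero_curve_raises(self, truth_spec):
        theta = np.linspace(0, 90, 500)
        curve = normalize_and_average([(theta, np.zeros_like(theta))], grid_size=200)
        with pytest.raises(CalibrationError):
            extract_passive_anchor(
                curve, truth_spec.passive_table.characteristic_angles, 0.45
            )

    def test_angles_outside_range_rejected(self, truth_spec):
        theta = np.linspace(0, 50, 500)
        curve = normalize_and_average([(theta, theta / 10.0)], grid_size=100)
        with pytest.raises(CalibrationError):
            extract_passive_anchor(curve, (0, 20, 40, 60, 80), 0.45)


class TestExtractActiveAnchor:
    def test_known_hinge_recovered_exactly(self):
        curve = hinge_curve(tau_a_max=20.0, vel_lim=15.0, vel_max=45.0)
        tau, vlim, slope, intercept = extract_active_anchor(curve, 0.45)
        assert tau == pytest.approx(20.0, rel=1e-6)
        assert vlim == pytest.approx(15.0, rel=1e-6)
        assert slope == pytest.approx(20.0 / 30.0, rel=1e-6)
        assert intercept == pytest.approx(-slope * vlim, rel=1e-6)

    def test_noisy_recovery_rate(self):
        """tau_a_max recovered within 5% in at least 18 of 20 noisy runs."""
        hits = 0
        d_tt = 0.45
        x = np.linspace(1.0, 85.0, 300)
        tau_true = np.clip(20.0 / 30.0 * (x - 15.0), 0.0, 20.0)
        force_true = tau_true * 2.0 / d_tt / G
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = force_true + rng.normal(0.0, 0.25, x.size)
            curve = normalize_and_average([(x, noisy)], grid_size=200, loess_degree=1)
            tau, *_ = extract_active_anchor(curve, d_tt)
            hits += abs(tau - 20.0) / 20.0 < 0.05
        assert hits >= 18

    def test_pure_linear_curve_raises(self):
        x = np.linspace(1.0, 60.0, 300)
        force = 0.5 * x
        curve = normalize_and_average([(x, force)], grid_size=150, loess_degree=1)
        with pytest.raises(CalibrationError):
            extract_active_anchor(curve, 0.45)


class TestBuildSpec:
    def test_anchors_survive_into_spec(self, truth_spec):
        table = truth_spec.passive_table
        anchors = {
            p: (table.tau_max[p], table.torque_ratios) for p in (40, 70, 100)
        }
        arows = {
            p: (
                truth_spec.active_table.rows[p].tau_a_max,
                truth_spec.active_table.rows[p].vel_lim,
                truth_spec.active_table.rows[p].vel_max,
            )
            for p in (40, 70, 100)
        }
        spec = build_spec(
            table.characteristic_angles, anchors, arows, 20.0, truth_spec.body
        )
        for p in (40, 70, 100):
            assert spec.passive_table.tau_max[p] == table.tau_max[p]
            assert spec.active_table.rows[p].tau_a_max == arows[p][0]

    def test_passive_only_gives_zero_active_table(self, truth_spec):
        table = truth_spec.passive_table
        anchors = {100: (table.tau_max[100], table.torque_ratios)}
        spec = build_spec(table.characteristic_angles, anchors, None, 20.0, truth_spec.body)
        for eta in range(0, 101, 10):
            assert spec.active_table.row(eta).tau_a_max == 0.0

    def test_non_monotone_anchors_rejected(self, truth_spec):
        table = truth_spec.passive_table
        anchors = {
            40: (20.0, table.torque_ratios),
            100: (10.0, table.torque_ratios),
        }
        with pytest.raises(ValidationError):
            build_spec(table.characteristic_angles, anchors, None, 20.0, truth_spec.body)


class TestFullRoundTrip:
    def test_noise_free_round_trip_recovers_spec(self, truth_spec, noise_free_sets):
        """The repo's central property: captures from a known device,
        calibrated, reproduce the device's anchors and per-frame forces."""
        pset, aset = noise_free_sets
        spec, rep = calibrate(
            group_by_percentage(pset, "passive"),
            group_by_percentage(aset, "active"),
            truth_spec.passive_table.characteristic_angles,
            truth_spec.assistance.psi_a,
            truth_spec.body,
        )
        for pct in (40, 70, 100):
            truth_tau = truth_spec.passive_table.tau_max[pct]
            assert rep.passive_anchors[pct] == pytest.approx(truth_tau, rel=1e-6)
            row = truth_spec.active_table.rows[pct]
            tau, vlim, vmax = rep.active_anchors[pct]
            assert tau == pytest.approx(row.tau_a_max, rel=1e-6)
            assert vlim == pytest.approx(row.vel_lim, rel=1e-6)
            assert vmax == pytest.approx(row.vel_max, rel=1e-6)
        worst = 0.0
        for sc in pset + aset:
            sim_t = simulate_capture(sc.capture, replace(truth_spec, assistance=sc.assistance))
            sim_c = simulate_capture(sc.capture, replace(spec, assistance=sc.assistance))
            worst = max(worst, float(np.max(np.abs(sim_t.chest_force_kgf - sim_c.chest_force_kgf))))
        assert worst < 1e-6
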