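"""Localization chain: medians, side sums, calibration, fixes, outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from volespace import telemetry
from volespace.geometry import SIDES, AntennaGeometry
from volespace.simulate import SignalNoiseModel, calibration_scans, simulate_movement, simulate_signals, simulate_voles
from volespace.simulate.signals import signal_array


class TestAggregateScan:
    def test_odd_length_median(self):
        scan = np.tile(np.arange(1.0, 8.0), (8, 1))
        assert np.allclose(telemetry.aggregate_scan(scan), 4.0)

    def test_median_robust_to_three_corruptions(self, rng):
        scan = np.tile(np.arange(1.0, 8.0), (8, 1))
        bad = scan.copy()
        bad[:, [0, 2, 5]] = np.inf
        # median breaks down only at 4 of 7 corrupted
        assert np.isfinite(telemetry.aggregate_scan(bad)).all()

    def test_matches_sort_and_pick_oracle(self, rng):
        scan = rng.normal(60, 10, (8, 7))
        oracle = np.sort(scan, axis=1)[:, 3]
        assert np.allclose(telemetry.aggregate_scan(scan), oracle)

    def test_missing_repeats_rejected(self):
        with pytest.raises(ValueError):
            telemetry.aggregate_scan(np.zeros((8, 5)))

    @given(
        hnp.arrays(
            np.float64,
            (8, 7),
            elements=st.floats(-120, 0, allow_nan=False),
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_median_between_min_and_max_per_antenna(self, scan):
        med = telemetry.aggregate_scan(scan)
        assert np.all(med >= scan.min(axis=1)) and np.all(med <= scan.max(axis=1))
        assert np.allclose(med, np.sort(scan, axis=1)[:, 3])


class TestSideSums:
    def test_equal_medians_give_3m(self, site):
        sums = telemetry.side_sums(np.full(8, 2.5), site.antenna_geometry)
        assert all(np.isclose(v, 7.5) for v in sums.values())

    def test_adjacent_side_dominates(self, site, noiseless, rng):
        # transmitter just inside the east side
        xmin, ymin, xmax, ymax = site.extent
        pos = np.array([[xmax + 5.0, (ymin + ymax) / 2]])
        arr = signal_array(pos, site, noiseless, rng)
        sums = telemetry.side_sums(
            telemetry.aggregate_scan(arr[0]), site.antenna_geometry
        )
        assert sums["E"] == max(sums.values())

    def test_matches_per_side_oracle(self, site, rng):
        med = rng.normal(50, 5, 8)
        sums = telemetry.side_sums(med, site.antenna_geometry)
        for s in SIDES:
            assert np.isclose(sums[s], sum(med[i] for i in site.antenna_geometry.sides[s]))

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            AntennaGeometry(
                antennas=np.zeros((8, 2)),
                sides={"N": (0, 1), "E": (1, 2, 3), "S": (3, 4, 5), "W": (5, 6, 7)},
            )


class TestCalibration:
    def test_linear_proportions_recovered(self, site):
        # proportions exactly linear in coordinate -> exact monotone map
        known = np.column_stack([np.linspace(0, 100, 5), np.linspace(0, 40, 5)])
        px = np.linspace(0.2, 0.8, 5)
        knots_x = telemetry._fit_axis(px, known[:, 0])
        assert np.allclose(np.interp(px, knots_x[:, 0], knots_x[:, 1]), known[:, 0])

    def test_center_maps_to_center(self, site, noiseless):
        known, scans = calibration_scans(site, noiseless, n_per_axis=3, seed=1)
        cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
        center = site.antenna_geometry.center
        arr = signal_array(center[None, :], site, noiseless, np.random.default_rng(0))
        x, y = telemetry.localize(arr[0], cal, site.antenna_geometry)
        assert np.allclose((x, y), center, atol=1e-6)

    def test_noiseless_heldout_accuracy(self, site, noiseless, rng):
        known, scans = calibration_scans(site, noiseless, n_per_axis=5, seed=1)
        cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
        assert cal.residual_rms_m < 0.5
        held = np.column_stack([rng.uniform(0, 100, 100), rng.uniform(0, 40, 100)])
        arr = signal_array(held, site, noiseless, rng)
        est = np.array(
            [telemetry.localize(a, cal, site.antenna_geometry) for a in arr]
        )
        err = np.hypot(*(est - held).T)
        # residual off-axis bias of the proportion method stays within a
        # few meters; the median is nearly exact
        assert np.median(err) < 2.0
        assert err.max() < 6.0

    def test_degenerate_span_rejected(self, site, noiseless):
        known = np.array([[0.0, 5.0], [50.0, 5.0], [100.0, 5.0]])
        scans = signal_array(known, site, noiseless, np.random.default_rng(0))
        with pytest.raises(ValueError):
            telemetry.fit_calibration(known, scans, site.antenna_geometry)

    def test_too_few_points_rejected(self, site):
        with pytest.raises(ValueError):
            telemetry.fit_calibration(np.zeros((2, 2)), np.zeros((2, 8, 7)), site.antenna_geometry)


class TestLocalize:
    def test_monotone_sweep(self, site, noiseless, rng):
        known, scans = calibration_scans(site, noiseless, n_per_axis=5, seed=1)
        cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
        xs = np.linspace(0, 100, 50)
        pos = np.column_stack([xs, np.full(50, 20.0)])
        arr = signal_array(pos, site, noiseless, rng)
        est = np.array([telemetry.localize(a, cal, site.antenna_geometry) for a in arr])
        assert np.all(np.diff(est[:, 0]) >= -1e-9)
        ys = np.linspace(0, 40, 50)
        pos = np.column_stack([np.full(50, 50.0), ys])
        arr = signal_array(pos, site, noiseless, rng)
        est = np.array([telemetry.localize(a, cal, site.antenna_geometry) for a in arr])
        assert np.all(np.diff(est[:, 1]) >= -1e-9)

    def test_no_signal_raises(self, site, noiseless):
        known, scans = calibration_scans(site, noiseless, seed=1)
        cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
        dead = np.full((8, 7), cal.background_db - 10.0)
        with pytest.raises(telemetry.NoSignalError):
            telemetry.localize(dead, cal, site.antenna_geometry)

    def test_translation_equivariance(self, noiseless, rng):
        from volespace.simulate import make_site

        site_a = make_site(seed=5)
        shift = np.array([250.0, -80.0])
        known, scans = calibration_scans(site_a, noiseless, n_per_axis=4, seed=2)
        cal_a = telemetry.fit_calibration(known, scans, site_a.antenna_geometry)
        geom_b = site_a.antenna_geometry.translated(*shift)
        cal_b = telemetry.fit_calibration(known + shift, scans, geom_b)
        pos = np.column_stack([rng.uniform(0, 100, 20), rng.uniform(0, 40, 20)])
        arr = signal_array(pos, site_a, noiseless, rng)
        est_a = np.array([telemetry.localize(a, cal_a, site_a.antenna_geometry) for a in arr])
        est_b = np.array([telemetry.localize(a, cal_b, geom_b) for a in arr])
        assert np.allclose(est_b, est_a + shift, atol=1e-6)

    def test_median_error_near_ten_meters(self, site, voles):
        # the default repeat-noise SD is calibrated to the field system's
        # reported ~10 m accuracy
        nm = SignalNoiseModel()
        known, scans = calibration_scans(site, nm, seed=4)
        cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
        traj = simulate_movement(voles[0], seed=5)
        st = simulate_signals(traj, site, nm, seed=5)
        fx = telemetry.localize_scans(st, cal, site.antenna_geometry)
        err = np.hypot(fx["x"] - traj.xy[:, 0], fx["y"] - traj.xy[:, 1])
        assert 7.0 < np.median(err) < 13.0

    def test_error_decreases_with_noise(self, site, voles):
        medians = []
        for sd in (6.0, 3.0, 1.0):
            nm = SignalNoiseModel(repeat_noise_sd=sd)
            known, scans = calibration_scans(site, nm, n_per_axis=4, seed=4)
            cal = telemetry.fit_calibration(known, scans, site.antenna_geometry)
            traj = simulate_movement(voles[1], seed=6)
            st = simulate_signals(traj, site, nm, seed=6)
            fx = telemetry.localize_scans(st, cal, site.antenna_geometry)
            medians.append(
                float(np.median(np.hypot(fx["x"] - traj.xy[:, 0], fx["y"] - traj.xy[:, 1])))
            )
        assert medians[0] > medians[1] > medians[2]


class TestOutlierFilter:
    @staticmethod
    def _track(xy):
        xy = np.asarray(xy, float)
        return pd.DataFrame(
            {
                "individual_id": "v",
                "timestamp_min": np.arange(len(xy)) * 20.0,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )

    def test_single_spike_removed(self):
        xy = [(i * 5.0, 0.0) for i in range(10)]
        xy[4] = (20.0, 80.0)
        out = telemetry.filter_outliers(self._track(xy))
        assert list(out["qc_flag"]) == ["ok"] * 4 + ["removed_outlier"] + ["ok"] * 5

    def test_no_removal_below_threshold(self, rng):
        xy = np.cumsum(rng.normal(0, 5, (50, 2)), axis=0)
        out = telemetry.filter_outliers(self._track(xy))
        assert (out["qc_flag"] == "ok").all()

    def test_short_track_warns(self):
        with pytest.warns(UserWarning):
            out = telemetry.filter_outliers(self._track([(0, 0), (1, 1)]))
        assert (out["qc_flag"] == "ok").all()

    def test_matches_neighbor_distance_oracle(self, rng):
        for _ in range(20):
            n = 40
            xy = np.cumsum(rng.normal(0, 8, (n, 2)), axis=0)
            spikes = rng.choice(n, 3, replace=False)
            xy[spikes] += rng.normal(0, 120, (3, 2))
            out = telemetry.filter_outliers(self._track(xy))
            flags = out["qc_flag"].to_numpy()
            for i in range(n):
                nb = [j for j in (i - 1, i + 1) if 0 <= j < n]
                far = all(np.hypot(*(xy[i] - xy[j])) > 50.0 for j in nb)
                assert (flags[i] == "removed_outlier") == far

    def test_idempotent_on_retained(self, rng):
        xy = np.cumsum(rng.normal(0, 6, (60, 2)), axis=0)
        xy[10] += 200.0
        once = telemetry.filter_outliers(self._track(xy))
        kept = once[once["qc_flag"] == "ok"].drop(columns="qc_flag")
        twice = telemetry.filter_outliers(kept)
        assert (twice["qc_flag"] == "ok").all()
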