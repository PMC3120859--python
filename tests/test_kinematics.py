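"""Velocity fields, expansion fits, rotation/shear tests, Fourier split."""

import numpy as np
import pandas as pd
import pytest

from rhizotrack.kinematics import (
    bin_field,
    compute_velocities,
    fit_expansion,
    frequency_split,
    interpolate_gaps,
    mean_step_displacement,
    profile_1d,
    radius_contraction,
    rotation_and_shear,
)
from rhizotrack.tracking import Trajectory, TrajectorySet
from tests.conftest import make_record


def _trajectory_records(paths, dt=10.0):
    """paths: list of (n_steps, 3) position arrays -> records + set."""
    records, trajs = [], []
    idx = 0
    for tid, path in enumerate(paths):
        ids = []
        for t, p in enumerate(path):
            records.append(make_record(idx, t * dt, p))
            ids.append(idx)
            idx += 1
        trajs.append(Trajectory(tid, ids))
    return records, TrajectorySet(trajectories=trajs)


def _cyl_from_records(records):
    from rhizotrack.registration import RootFrame, to_root_frame

    frame = RootFrame.static([0.0, 0.0, 0.0], n_frames=1)
    pts = np.array([r.centroid for r in records])
    return to_root_frame(pts, frame)


class TestComputeVelocities:
    def test_static_nuclei_zero(self):
        paths = [np.tile([3.0, 50.0, 4.0], (5, 1))]
        records, ts = _trajectory_records(paths)
        vel = compute_velocities(ts, records, _cyl_from_records(records))
        assert np.allclose(vel[["v_m", "v_rho", "rho_v_theta"]], 0.0)

    def test_pure_rotation_only_theta_component(self):
        omega = 1e-3  # rad/min
        rho = 20.0
        t = np.arange(6) * 10.0
        theta = omega * t
        # theta measured from +z toward -x
        path = np.column_stack(
            [-rho * np.sin(theta), np.full_like(t, 100.0), rho * np.cos(theta)]
        )
        records, ts = _trajectory_records([path])
        vel = compute_velocities(ts, records, _cyl_from_records(records))
        np.testing.assert_allclose(vel["rho_v_theta"], rho * omega, rtol=1e-6)
        np.testing.assert_allclose(vel["v_m"], 0.0, atol=1e-9)
        np.testing.assert_allclose(vel["v_rho"], 0.0, atol=1e-9)

    def test_theta_wraparound_continuous(self):
        rho = 10.0
        thetas = np.array([np.pi - 0.05, -np.pi + 0.05])  # crossing pi
        path = np.column_stack(
            [-rho * np.sin(thetas), [50.0, 50.0], rho * np.cos(thetas)]
        )
        records, ts = _trajectory_records([path])
        vel = compute_velocities(ts, records, _cyl_from_records(records))
        # 0.1 rad step over 10 min, no 2*pi jump
        np.testing.assert_allclose(
            vel["rho_v_theta"], rho * 0.01, rtol=1e-6
        )

    def test_excluded_records_dropped(self):
        paths = [np.tile([0.0, 50.0, 5.0], (4, 1))]
        records, ts = _trajectory_records(paths)
        vel = compute_velocities(
            ts, records, _cyl_from_records(records), exclude_records={1}
        )
        assert len(vel) == 1  # only the step between records 2 and 3


class TestBinField:
    def test_single_bin_unmasked(self):
        samples = pd.DataFrame(
            {
                "m_mid": np.full(50, 102.0),
                "rho_mid": np.full(50, 10.0),
                "v_m": np.random.default_rng(0).normal(0.1, 0.01, 50),
                "v_rho": np.zeros(50),
                "rho_v_theta": np.zeros(50),
            }
        )
        field = bin_field(samples, bin_width=5.0, min_count=36)
        assert field.mask.sum() == 1

    def test_min_count_boundary(self):
        def make(n):
            return pd.DataFrame(
                {
                    "m_mid": np.full(n, 10.0),
                    "rho_mid": np.zeros(n),
                    "v_m": np.zeros(n),
                    "v_rho": np.zeros(n),
                    "rho_v_theta": np.zeros(n),
                }
            )

        assert not bin_field(make(35), min_count=36).mask.any()
        assert bin_field(make(36), min_count=36).mask.any()

    def test_median_equals_direct_sort(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2.0, 1.0, 101)
        samples = pd.DataFrame(
            {
                "m_mid": np.full(101, 7.0),
                "rho_mid": np.zeros(101),
                "v_m": v,
                "v_rho": v,
                "rho_v_theta": v,
            }
        )
        field = bin_field(samples, bin_width=5.0, min_count=1)
        m, med, q25, q75 = profile_1d(field, "v_m")
        assert med[0] == pytest.approx(np.median(v))
        assert q25[0] == pytest.approx(np.percentile(v, 25))


class TestFitExpansion:
    def test_exact_linear_field(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(80, 300, 200)
        slope, icpt = 5e-4, -0.045
        samples = pd.DataFrame(
            {
                "m_mid": m,
                "rho_mid": np.zeros(200),
                "v_m": icpt + slope * m,
                "v_rho": np.zeros(200),
                "rho_v_theta": np.zeros(200),
            }
        )
        fit = fit_expansion(samples)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(icpt, abs=1e-12)

    def test_zero_field_zero_slope(self):
        m = np.linspace(80, 300, 50)
        samples = pd.DataFrame(
            {
                "m_mid": m,
                "rho_mid": np.zeros(50),
                "v_m": np.zeros(50),
                "v_rho": np.zeros(50),
                "rho_v_theta": np.zeros(50),
            }
        )
        assert fit_expansion(samples).slope == pytest.approx(0.0, abs=1e-15)

    def test_insufficient_samples_raise(self):
        samples = pd.DataFrame(
            {
                "m_mid": [100.0] * 3,
                "rho_mid": [0.0] * 3,
                "v_m": [0.0] * 3,
                "v_rho": [0.0] * 3,
                "rho_v_theta": [0.0] * 3,
            }
        )
        with pytest.raises(ValueError):
            fit_expansion(samples)


class TestRotationAndShear:
    def _samples(self, rng, omega=0.0, twist=0.0, n=2000):
        m = rng.uniform(0, 300, n)
        rho = rng.uniform(2, 50, n)
        noise = rng.normal(0, 0.02, (n, 3))
        v_theta = omega + twist * m
        return pd.DataFrame(
            {
                "m_mid": m,
                "rho_mid": rho,
                "v_m": noise[:, 0],
                "v_rho": noise[:, 1],
                "rho_v_theta": rho * v_theta + noise[:, 2],
            }
        )

    def test_rigid_rotation_recovered_no_twist(self):
        rng = np.random.default_rng(3)
        omega = 6e-4
        samples = self._samples(rng, omega=omega)
        out = rotation_and_shear(samples)
        rho_bar = samples["rho_mid"].mean()
        est = out["mean_rho_v_theta"][0]
        assert abs(est - rho_bar * omega) / (rho_bar * omega) < 0.1
        lo, hi = out["twist_slope_vtheta_on_m"][1:]
        assert lo <= 0.0 <= hi

    def test_pure_stretch_no_rotation(self):
        rng = np.random.default_rng(4)
        samples = self._samples(rng, omega=0.0)
        samples["v_m"] = 5e-4 * samples["m_mid"]
        out = rotation_and_shear(samples)
        for key in ("mean_rho_v_theta", "mean_v_rho"):
            mean, lo, hi = out[key]
            se = (hi - lo) / (2 * 1.96)
            assert abs(mean) <= 3 * se

    def test_imposed_twist_detected(self):
        rng = np.random.default_rng(5)
        samples = self._samples(rng, omega=0.0, twist=2e-5)
        out = rotation_and_shear(samples)
        lo, hi = out["twist_slope_vtheta_on_m"][1:]
        assert lo > 0.0  # CI excludes zero


class TestFrequencySplit:
    def test_constant_trajectory(self):
        t = np.arange(16) * 10.0
        low, high = frequency_split(t, np.full(16, 7.0))
        np.testing.assert_allclose(low, 7.0, atol=1e-12)
        np.testing.assert_allclose(high, 0.0, atol=1e-12)

    def test_fast_sinusoid_lands_in_high_band(self):
        t = np.arange(60) * 10.0  # 10 hours
        signal = np.sin(2 * np.pi * (1.0 / 60.0) * t)  # 1 cycle/hr in minutes
        low, high = frequency_split(t, signal, cutoff_hr=0.23)
        assert np.abs(low).max() < 1e-9
        np.testing.assert_allclose(high, signal, atol=1e-9)

    def test_drift_plus_jitter_separated(self):
        t = np.arange(120) * 10.0
        drift = np.sin(2 * np.pi * (0.05 / 60.0) * t)
        jitter = 0.3 * np.sin(2 * np.pi * (1.0 / 60.0) * t)
        low, high = frequency_split(t, drift + jitter, cutoff_hr=0.23)
        np.testing.assert_allclose(low, drift, atol=1e-9)
        np.testing.assert_allclose(high, jitter, atol=1e-9)
        np.testing.assert_allclose(low + high, drift + jitter, atol=1e-9)

    def test_additivity_multidimensional(self):
        rng = np.random.default_rng(6)
        t = np.arange(40) * 10.0
        vals = rng.normal(0, 1, (40, 3))
        low, high = frequency_split(t, vals)
        np.testing.assert_allclose(low + high, vals, atol=1e-9)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            frequency_split(np.arange(3) * 10.0, np.zeros(3))

    def test_nonuniform_rejected_and_interpolation_helper(self):
        t = np.array([0.0, 10.0, 30.0, 40.0])
        with pytest.raises(ValueError):
            frequency_split(t, np.zeros(4))
        grid, vals, interped = interpolate_gaps(t, np.array([0, 1, 3, 4.0]), 10.0)
        np.testing.assert_allclose(grid, [0, 10, 20, 30, 40.0])
        assert interped.tolist() == [False, False, True, False, False]
        np.testing.assert_allclose(vals, [0, 1, 2, 3, 4.0])


class TestJitterIsotropyAndDrift:
    def test_jitter_only_fixture_mean_velocities_near_zero(self):
        """On pure-jitter trajectories all mean velocity components stay
        within 3 SE of zero."""
        rng = np.random.default_rng(7)
        paths = []
        for k in range(40):
            base = np.array([rng.uniform(-10, 10), rng.uniform(20, 200), rng.uniform(-10, 10)])
            steps = rng.normal(0, 0.6, (12, 3))
            paths.append(base + np.cumsum(steps, axis=0))
        records, ts = _trajectory_records(paths)
        vel = compute_velocities(ts, records, _cyl_from_records(records))
        for comp in ("v_m", "v_rho", "rho_v_theta"):
            x = vel[comp].to_numpy()
            se = x.std(ddof=1) / np.sqrt(len(x))
            assert abs(x.mean()) < 3 * se + 1e-3

    def test_mean_step_displacement_recovers_jitter_scale(self):
        rng = np.random.default_rng(8)
        paths = []
        target_mean = 1.1
        for k in range(60):
            base = np.array([0.0, rng.uniform(20, 200), 8.0])
            mags = rng.gamma((1.1 / 0.8) ** 2, 0.8**2 / 1.1, 15)
            dirs = rng.normal(0, 1, (15, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            paths.append(base + np.cumsum(mags[:, None] * dirs, axis=0))
        records, ts = _trajectory_records(paths)
        est, n = mean_step_displacement(
            ts, records, _cyl_from_records(records), lateral_size_max=99.0
        )
        assert n > 500
        assert abs(est - target_mean) / target_mean < 0.1


class TestRadiusContraction:
    def test_counts_outer_nuclei_per_frame(self):
        records = []
        for t in range(3):
            for rho in (10.0, 60.0, 70.0):
                records.append(
                    make_record(len(records), t * 10.0, [rho, 100.0, 0.0])
                )
        cyl = _cyl_from_records(records)
        out = radius_contraction(cyl, records, rho_threshold=55.0)
        assert (out["n_outer"] == 2).all()
        assert len(out) == 3
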