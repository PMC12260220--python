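"""Feature extraction against closed-form oracles on analytic paths."""

import numpy as np
import pytest
from scipy.signal import get_window
from scipy.spatial.transform import Rotation

import rootkin as rk
from rootkin.features import (
    FeatureConfig,
    horizontal_excursion,
    spectral_entropy_of,
)


def circle_path(R, n=800, turns=0.5, plane=(0, 2)):
    """Planar arc of radius R traced at constant speed."""
    theta = np.linspace(0, 2 * np.pi * turns, n)
    xyz = np.zeros((n, 3))
    xyz[:, plane[0]] = R * np.cos(theta)
    xyz[:, plane[1]] = R * np.sin(theta)
    return xyz


def helix_path(a, b, n=2000, turns=10):
    """Helix of radius a and pitch parameter b (z = b * angle)."""
    theta = np.linspace(0, 2 * np.pi * turns, n)
    return np.column_stack([a * np.cos(theta), b * theta, a * np.sin(theta)])


class TestStepKinematics:
    def test_uniform_steps_give_constant_velocity_zero_acceleration(
        self, make_traj
    ):
        xyz = np.zeros((100, 3))
        xyz[:, 1] = -np.arange(100) * 0.01
        kin = rk.step_kinematics(make_traj(xyz))
        np.testing.assert_allclose(kin["velocity"], 0.01 / 180.0, rtol=1e-12)
        np.testing.assert_allclose(kin["acceleration"], 0.0, atol=1e-15)

    def test_stationary_tip_all_zero(self, make_traj):
        kin = rk.step_kinematics(make_traj(np.zeros((50, 3))))
        assert not kin["distance"].any()
        assert not kin["velocity"].any()

    def test_constant_acceleration_matches_finite_difference_form(
        self, make_traj
    ):
        # 1-D path x = 0.5*g*t^2: step velocity (forward difference) is
        # g*(t_i + t_{i+1})/2, whose forward difference is exactly g*dt/dt = g.
        g = 1e-7
        t = np.arange(60) * 180.0
        xyz = np.zeros((60, 3))
        xyz[:, 0] = 0.5 * g * t ** 2
        kin = rk.step_kinematics(make_traj(xyz))
        np.testing.assert_allclose(kin["acceleration"], g, rtol=1e-9)


class TestSegmentationAngles:
    @pytest.mark.parametrize(
        "third_point, expected",
        [([2, 0, 0], 0.0), ([1, 1, 0], 90.0), ([0, 0, 0], 180.0)],
        ids=["collinear", "right-angle", "reversal"],
    )
    def test_canonical_turns(self, make_traj, third_point, expected):
        traj = make_traj([[0, 0, 0], [1, 0, 0], third_point])
        angles = rk.segmentation_angles(traj)
        assert angles[0] == pytest.approx(expected, abs=1e-9)

    def test_zero_length_segment_yields_nan(self, make_traj):
        traj = make_traj([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]])
        angles = rk.segmentation_angles(traj)
        assert np.isnan(angles[0]) and np.isnan(angles[1])

    def test_angles_bounded(self):
        rng = np.random.default_rng(2)
        traj = rk.Trajectory("r", "synthetic", t=np.arange(200) * 180.0,
                             xyz=rng.normal(size=(200, 3)))
        angles = rk.segmentation_angles(traj)
        assert np.all((angles >= 0) & (angles <= 180))


class TestGrowthRates:
    def test_straight_growth_one_cm_per_day(self, straight_trajectory):
        absolute, relative = rk.growth_rates(straight_trajectory)
        assert absolute == pytest.approx(1.0, rel=1e-9)

    def test_relative_rate_first_day_quarter_with_4cm_baseline(self, make_traj):
        # 2-day straight path at 1 cm/day over a 4 cm initial root:
        # day-1 increment 1/4, day-2 increment 1/5 -> mean 0.225 /day.
        n = 2 * 480 + 1
        xyz = np.zeros((n, 3))
        xyz[:, 1] = -np.linspace(0, 2, n)
        absolute, relative = rk.growth_rates(make_traj(xyz))
        assert relative == pytest.approx((0.25 + 0.2) / 2, rel=1e-9)

    def test_helix_absolute_rate_matches_arc_length(self):
        # speed = sqrt((a*omega)^2 + c^2) is constant on a helix
        p = rk.GrowthParams(axial_rate=1.0, nutation_amplitude=0.2,
                            nutation_period=90.0)
        traj = rk.generate_trajectory(p)
        omega = 2 * np.pi / (90 * 60)
        v = np.hypot(0.2 * omega, 1.0 / 86400.0)  # cm/s
        absolute, _ = rk.growth_rates(traj)
        # chord-length sum underestimates the arc by (dtheta)^2/24 ~ 0.2%
        assert absolute == pytest.approx(v * 86400, rel=3e-3)


class TestHourlyVelocity:
    def test_uniform_steps(self, make_traj):
        xyz = np.zeros((41, 3))
        xyz[:, 2] = np.arange(41) * 0.01  # 0.01 cm per 3 min
        assert rk.average_hourly_tip_velocity(make_traj(xyz)) == pytest.approx(0.2)

    def test_equals_mean_step_rate_on_uniform_sampling(self, helix_trajectory):
        kin = rk.step_kinematics(helix_trajectory)
        expected = kin["distance"].mean() * 3600.0 / 180.0
        got = rk.average_hourly_tip_velocity(helix_trajectory)
        assert got == pytest.approx(expected, rel=1e-9)


class TestMainComponent:
    def test_straight_path_is_fixed_point(self, straight_trajectory):
        mc = rk.main_growth_component(straight_trajectory, 5400.0)
        np.testing.assert_allclose(mc, straight_trajectory.xyz, atol=1e-12)

    def test_helix_window_one_period_recovers_axis(self, helix_trajectory):
        mc = rk.main_growth_component(helix_trajectory, 90 * 60.0)
        interior = slice(60, -60)
        horiz = mc[interior][:, [0, 2]]
        axis = helix_trajectory.xyz[:, [0, 2]].mean(axis=0)
        # smoothed path hugs the helix axis to within 5% of the radius
        assert np.abs(horiz - axis).max() < 0.05 * 0.2

    def test_output_length_matches_input(self, helix_trajectory):
        mc = rk.main_growth_component(helix_trajectory, 7200.0)
        assert mc.shape == helix_trajectory.xyz.shape

    def test_window_below_three_samples_rejected(self, helix_trajectory):
        with pytest.raises(ValueError, match="3 samples"):
            rk.main_growth_component(helix_trajectory, 200.0)


class TestNutationAmplitude:
    def test_straight_path_zero(self, straight_trajectory):
        mc = rk.main_growth_component(straight_trajectory, 7200.0)
        amp = rk.nutation_amplitude(straight_trajectory, mc)
        np.testing.assert_allclose(amp, 0.0, atol=1e-12)

    def test_helix_recovers_radius(self, helix_trajectory):
        mc = rk.main_growth_component(helix_trajectory, 90 * 60.0)
        amp = rk.nutation_amplitude(helix_trajectory, mc)
        interior = amp[60:-60]
        assert np.median(interior) == pytest.approx(0.2, rel=0.1)

    def test_length_mismatch_rejected(self, helix_trajectory):
        with pytest.raises(ValueError, match="length"):
            rk.nutation_amplitude(helix_trajectory,
                                  helix_trajectory.xyz[:-1])


class TestMainNutationPeriod:
    def test_sinusoid_period_recovered_within_one_bin(self):
        n = 3361
        dt = 180.0
        t = np.arange(n) * dt
        sig = 0.1 + 0.05 * np.sin(2 * np.pi * t / 5400.0)
        period, _ = rk.main_nutation_period(sig, dt)
        f0 = 1 / 5400.0
        df = 1 / (n * dt)
        assert abs(1 / (period * 60.0) - f0) <= df

    def test_dominant_peak_wins_over_smaller_harmonic(self):
        t = np.arange(3361) * 180.0
        sig = (0.05 * np.sin(2 * np.pi * t / 5400.0)
               + 0.01 * np.sin(2 * np.pi * t / 1800.0))
        period, _ = rk.main_nutation_period(sig, 180.0)
        assert period == pytest.approx(90.0, abs=2.0)

    def test_doubling_amplitude_quadruples_peak_power(self):
        t = np.arange(2048) * 180.0
        base = np.sin(2 * np.pi * t / 5400.0)
        _, p1 = rk.main_nutation_period(base, 180.0)
        _, p2 = rk.main_nutation_period(2 * base, 180.0)
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rk.main_nutation_period(np.full(64, 0.3), 180.0)


def welch_entropy_oracle(x, nperseg=256, window="hann"):
    """Independent Welch + Shannon-entropy implementation: manual
    segmentation, tapering and periodogram averaging."""
    x = np.asarray(x, float) - np.mean(x)
    nper = min(nperseg, len(x) // 2)
    step = nper // 2
    win = get_window(window, nper)
    segments = []
    start = 0
    while start + nper <= len(x):
        seg = (x[start:start + nper] - x[start:start + nper].mean()) * win
        segments.append(np.abs(np.fft.rfft(seg)) ** 2)
        start += step
    psd = np.mean(segments, axis=0)
    p = psd / psd.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestSpectralEntropy:
    def test_pure_sinusoid_concentrated_spectrum(self):
        t = np.arange(3361) * 180.0
        sig = np.sin(2 * np.pi * t / 5400.0)
        h = spectral_entropy_of(sig, fs=1 / 180.0)
        oracle = welch_entropy_oracle(sig)
        n_bins = 129
        assert h == pytest.approx(oracle, rel=0.10)
        assert h < 0.3 * np.log2(n_bins)  # far below the flat-spectrum bound

    def test_white_noise_near_log2_bins(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=4096)
        h = spectral_entropy_of(sig, fs=1 / 180.0)
        oracle = welch_entropy_oracle(sig)
        assert h == pytest.approx(oracle, rel=0.10)
        assert h == pytest.approx(np.log2(129), rel=0.10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        sig = rng.normal(size=1024) + np.sin(np.arange(1024) / 5.0)
        a = spectral_entropy_of(sig, fs=1.0)
        b = spectral_entropy_of(10 * sig, fs=1.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_entropy_bounded_by_log2_bins(self, helix_trajectory):
        mc = rk.main_growth_component(helix_trajectory, 5400.0)
        h = rk.spectral_entropy(helix_trajectory, mc)
        assert 0 <= h <= np.log2(129)

    def test_all_zero_signal_entropy_zero(self, straight_trajectory):
        mc = rk.main_growth_component(straight_trajectory, 7200.0)
        assert rk.spectral_entropy(straight_trajectory, mc) == 0.0


class TestCurvature:
    def test_straight_line_zero(self, make_traj):
        xyz = np.zeros((50, 3))
        xyz[:, 0] = np.arange(50) * 0.3
        k = rk.curvature_series(make_traj(xyz))
        np.testing.assert_allclose(k, 0.0, atol=1e-12)

    @pytest.mark.parametrize("R", [0.5, 2.0])
    def test_circle_curvature_inverse_radius(self, make_traj, R):
        traj = make_traj(circle_path(R, n=1500, turns=2))
        k = rk.curvature_series(traj)
        np.testing.assert_allclose(k[2:-2], 1 / R, rtol=0.02)

    def test_helix_curvature_closed_form(self, make_traj):
        a, b = 0.4, 0.1
        traj = make_traj(helix_path(a, b, n=4000, turns=8))
        k = rk.curvature_series(traj)
        np.testing.assert_allclose(k[2:-2], a / (a ** 2 + b ** 2), rtol=0.02)

    def test_total_variation_zero_on_constant_curvature(self, make_traj):
        k = rk.curvature_series(make_traj(circle_path(1.0, n=1000, turns=2)))
        assert rk.total_variation_curvature(k[2:-2]) < 0.02

    def test_total_variation_alternating_hand_sum(self):
        k = np.array([0.0, 0.3, 0.0, 0.3, 0.0, 0.3])
        assert rk.total_variation_curvature(k) == pytest.approx(5 * 0.3)


class TestTortuosity:
    def test_straight_line_is_one(self, make_traj):
        xyz = np.zeros((30, 3))
        xyz[:, 1] = -np.arange(30) * 0.1
        assert rk.tortuosity(make_traj(xyz)) == pytest.approx(1.0)

    def test_semicircle_is_pi_over_two(self, make_traj):
        traj = make_traj(circle_path(1.0, n=2000, turns=0.5))
        assert rk.tortuosity(traj) == pytest.approx(np.pi / 2, rel=1e-4)

    def test_closed_path_rejected(self, make_traj):
        xyz = circle_path(1.0, n=100, turns=1.0)
        xyz[-1] = xyz[0]
        traj = make_traj(xyz)
        with pytest.raises(ValueError, match="start equals end"):
            rk.tortuosity(traj)

    def test_monotone_in_lateral_noise(self, make_traj):
        # adding zero-mean lateral noise lengthens the path monotonically
        # in expectation while the chord stays put
        rng = np.random.default_rng(1)
        base = np.zeros((500, 3))
        base[:, 1] = -np.linspace(0, 5, 500)
        means = []
        for sd in (0.0, 0.02, 0.05):
            vals = []
            for _ in range(20):
                noisy = base + rng.normal(0, sd, size=base.shape) * [1, 0, 1]
                vals.append(rk.tortuosity(make_traj(noisy)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestRigidMotionInvariance:
    def test_features_invariant_to_rotation_and_translation(self):
        p = rk.GrowthParams(axial_rate=1.2, nutation_amplitude=0.2,
                            nutation_period=80.0, radial_asymmetry=0.3,
                            noise_sd=0.01, seed=3)
        traj = rk.generate_trajectory(p)
        rot = Rotation.from_euler("xyz", [20, 35, -50], degrees=True)
        moved = rk.Trajectory(
            "rot", "synthetic", t=traj.t,
            xyz=rot.apply(traj.xyz) + np.array([3.0, -2.0, 1.0]),
        )
        for fn in (lambda tr: rk.step_kinematics(tr)["distance"],
                   rk.segmentation_angles,
                   rk.curvature_series):
            np.testing.assert_allclose(fn(moved), fn(traj), rtol=1e-8,
                                       atol=1e-12)
        assert rk.tortuosity(moved) == pytest.approx(rk.tortuosity(traj),
                                                     rel=1e-9)
        mc_a = rk.main_growth_component(traj, 4800.0)
        mc_b = rk.main_growth_component(moved, 4800.0)
        np.testing.assert_allclose(
            rk.nutation_amplitude(moved, mc_b),
            rk.nutation_amplitude(traj, mc_a), atol=1e-9,
        )


class TestExtractFeatures:
    def test_classifier_feature_names_present(self, helix_trajectory):
        feats = rk.extract_features(helix_trajectory)
        for name in rk.CLASSIFIER_FEATURES:
            assert name in feats

    def test_deterministic(self, helix_trajectory):
        a = rk.extract_features(helix_trajectory)
        b = rk.extract_features(helix_trajectory)
        assert a == b

    def test_generator_round_trip_recovers_planted_values(self):
        p = rk.GrowthParams(axial_rate=1.0, nutation_amplitude=0.2,
                            nutation_period=90.0, radial_asymmetry=0.3)
        feats = rk.extract_features(rk.generate_trajectory(p))
        assert feats["period of main nutation"] == pytest.approx(90.0, abs=3.0)
        assert feats["mean nutation amplitude"] == pytest.approx(0.2, rel=0.1)

    def test_feature_table_has_condition_labels(self):
        trajs, labels = rk.simulate_condition_trajectories(
            n_individual=2, n_social=2, seed=0)
        df = rk.feature_table(trajs, labels=labels)
        assert df.shape[0] == 4
        assert set(df["condition"]) == {"individual", "social"}
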