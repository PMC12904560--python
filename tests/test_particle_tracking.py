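import numpy as np
import pytest

import nvflow as nv
from nvflow import particle_tracking as pt


def synthetic_streaks(slope, n_s=48, n_t=48, seed=0):
    """Non-periodic parallel streaks of known slope (rows per column).

    A periodic grating would alias in angle (shears displacing by an integer
    number of periods also align), so the streak profile is a smoothed
    random pattern."""
    from scipy.ndimage import gaussian_filter1d
    rng = np.random.default_rng(seed)
    profile = gaussian_filter1d(rng.random(4 * (n_s + n_t)), 2.0)
    rows = np.arange(n_s)[:, None]
    cols = np.arange(n_t)[None, :] - n_t // 2
    phase = rows - slope * cols + 2 * (n_s + n_t)
    return np.interp(phase.ravel(), np.arange(profile.size),
                     profile).reshape(n_s, n_t)


class TestVesselSegment:
    def test_zero_length_edge_rejected(self, meta):
        with pytest.raises(ValueError, match="zero-length"):
            pt.VesselSegment(points=[(5, 5), (5, 5)], metadata=meta)

    def test_arclength_physical(self, meta):
        seg = pt.VesselSegment(points=[(0, 0), (3, 4)], metadata=meta)
        assert seg.length == pytest.approx(5 * meta.pixel_size_z, rel=1e-9)


class TestKymograph:
    def test_static_scene_columns_identical(self, meta):
        scene = nv.SyntheticScene(metadata=meta, dims=(40, 60, 6),
                                  rpe_depth_index=34, vessels=[],
                                  noise_sigma=0.0, seed=1)
        vol, _ = nv.simulate_dyc_series(scene)
        seg = pt.VesselSegment(points=[(5, 10), (25, 40)], metadata=meta)
        kym = pt.build_kymograph(vol, seg)
        np.testing.assert_allclose(kym.values,
                                   kym.values[:, :1] * np.ones(6), rtol=1e-10)
        assert kym.dt == meta.interscan_time

    def test_segment_exits_frame_rejected(self, meta):
        scene = nv.SyntheticScene(metadata=meta, dims=(40, 60, 4),
                                  rpe_depth_index=34, vessels=[], seed=1)
        vol, _ = nv.simulate_dyc_series(scene)
        seg = pt.VesselSegment(points=[(5, 10), (80, 40)], metadata=meta)
        with pytest.raises(ValueError, match="exits the frame"):
            pt.build_kymograph(vol, seg)

    def test_streak_slope_matches_configured_speed(self, meta):
        v = 1.0e-3
        vessel = nv.straight_vessel(metadata=meta, dims=(64, 110),
                                    angle_alpha=1.07, radius=10e-6,
                                    center=(30, 55), speed_profile=v,
                                    backscatter_baseline=2.0)
        scene = nv.SyntheticScene(metadata=meta, dims=(64, 110, 120),
                                  rpe_depth_index=56, vessels=[vessel],
                                  noise_sigma=0.05, seed=3)
        vol, _ = nv.simulate_dyc_series(scene)
        seg = pt.VesselSegment(points=vessel.centerline, metadata=meta)
        kym = pt.build_kymograph(vol, seg)
        res = pt.radon_dominant_angle(kym.values[:, :100], kym.ds, kym.dt)
        v_hat = pt.angle_to_velocity(res)
        assert abs(v_hat - 1.0) < 0.05


class TestRadonDominantAngle:
    def test_line_at_45_degrees_isotropic_scaling(self):
        window = synthetic_streaks(slope=1.0)
        # v_scale = ds/dt makes the pixel grid isotropic for the angle
        res = pt.radon_dominant_angle(window, ds=1.0, dt=1.0, v_scale=1.0)
        # textured streaks carry an intrinsic sub-degree estimator bias
        assert np.rad2deg(res.theta) == pytest.approx(45.0, abs=1.0)

    def test_line_at_30_degrees_recovered_on_grid(self):
        slope = 1.0 / np.tan(np.deg2rad(30.0))
        window = synthetic_streaks(slope=slope)
        res = pt.radon_dominant_angle(window, ds=1.0, dt=1.0, v_scale=1.0)
        assert np.rad2deg(res.theta) == pytest.approx(30.0, abs=1.0)

    def test_constant_window_flagged_not_raised(self):
        res = pt.radon_dominant_angle(np.full((16, 16), 3.0), ds=1.0, dt=1.0)
        assert not res.reliable
        assert res.confidence == 1.0

    def test_pure_noise_low_confidence(self):
        rng = np.random.default_rng(0)
        window = rng.random((24, 24))
        res = pt.radon_dominant_angle(window, ds=1.0, dt=1.0, v_scale=1.0)
        streaky = pt.radon_dominant_angle(synthetic_streaks(1.0, n_s=24, n_t=24),
                                          ds=1.0, dt=1.0, v_scale=1.0)
        assert res.confidence < streaky.confidence

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="8 x 8"):
            pt.radon_dominant_angle(np.ones((4, 20)), ds=1.0, dt=1.0)


class TestAngleToVelocity:
    def test_unit_slope_gives_scale_velocity(self):
        res = pt.StreakAngleResult(theta=np.deg2rad(45.0), confidence=5.0,
                                   window_start=0, window_stop=10,
                                   v_scale=1e-3)
        assert pt.angle_to_velocity(res) == pytest.approx(1.0)

    def test_streaks_parallel_to_time_axis_mean_stationary(self):
        res = pt.StreakAngleResult(theta=np.deg2rad(90.0), confidence=5.0,
                                   window_start=0, window_stop=10,
                                   v_scale=1e-3)
        assert pt.angle_to_velocity(res) == pytest.approx(0.0, abs=1e-9)

    def test_guard_band_yields_nan(self):
        res = pt.StreakAngleResult(theta=np.deg2rad(0.5), confidence=5.0,
                                   window_start=0, window_stop=10,
                                   v_scale=1e-3, reliable=False)
        assert np.isnan(pt.angle_to_velocity(res))

    def test_orientation_sign_applies_flow_convention(self):
        res = pt.StreakAngleResult(theta=np.deg2rad(45.0), confidence=5.0,
                                   window_start=0, window_stop=10,
                                   v_scale=1e-3)
        assert pt.angle_to_velocity(res, orientation_sign=-1.0) == pytest.approx(-1.0)


@pytest.fixture(scope="module")
def _moving_kymo_holder():
    return {}


class TestSlidingWindow:
    @pytest.fixture()
    def moving_kymo(self, meta, _moving_kymo_holder):
        if "kymo" in _moving_kymo_holder:
            return _moving_kymo_holder["kymo"]
        vessel = nv.straight_vessel(metadata=meta, dims=(64, 110),
                                    angle_alpha=1.07, radius=10e-6,
                                    center=(30, 55), speed_profile=1.5e-3,
                                    backscatter_baseline=2.0)
        scene = nv.SyntheticScene(metadata=meta, dims=(64, 110, 300),
                                  rpe_depth_index=56, vessels=[vessel],
                                  galvo_ramp=0.1, noise_sigma=0.2, seed=5)
        vol, _ = nv.simulate_dyc_series(scene)
        seg = pt.VesselSegment(points=vessel.centerline, metadata=meta)
        _moving_kymo_holder["kymo"] = pt.build_kymograph(vol, seg)
        return _moving_kymo_holder["kymo"]

    def test_sample_count(self, moving_kymo):
        trace = pt.sliding_window_velocity(moving_kymo, window_frames=100)
        assert len(trace) == 300 - 100 + 1
        # 100-frame window spans 0.77 s of the published protocol
        assert 100 * moving_kymo.dt == pytest.approx(0.77)
        np.testing.assert_allclose(np.diff(trace.times), moving_kymo.dt)

    def test_constant_velocity_trace_constant(self, moving_kymo):
        trace = pt.sliding_window_velocity(moving_kymo, window_frames=100)
        vals = trace.values[trace.reliable]
        # median within 5%; the upper tail carries occasional windows locked
        # onto partially aliased fine speckle (see the methods note)
        assert np.median(np.abs(vals - 1.5)) < 0.075
        assert np.percentile(np.abs(vals - 1.5), 75) < 0.15

    def test_window_longer_than_series_rejected(self, moving_kymo):
        with pytest.raises(ValueError, match="exceeds"):
            pt.sliding_window_velocity(moving_kymo, window_frames=400)

    def test_axis_scaling_invariance(self, meta):
        """Doubling the row sampling step leaves the recovered velocity
        unchanged within grid quantisation."""
        vessel = nv.straight_vessel(metadata=meta, dims=(64, 110),
                                    angle_alpha=1.07, radius=10e-6,
                                    center=(30, 55), speed_profile=1.2e-3,
                                    backscatter_baseline=2.0)
        scene = nv.SyntheticScene(metadata=meta, dims=(64, 110, 140),
                                  rpe_depth_index=56, vessels=[vessel],
                                  noise_sigma=0.05, seed=9)
        vol, _ = nv.simulate_dyc_series(scene)
        seg = pt.VesselSegment(points=vessel.centerline, metadata=meta)
        out = []
        for ds in (2e-6, 4e-6):
            kym = pt.build_kymograph(vol, seg, ds=ds)
            res = pt.radon_dominant_angle(kym.values[:, :100], kym.ds, kym.dt)
            out.append(pt.angle_to_velocity(res))
        assert out[0] == pytest.approx(1.2, rel=0.05)
        assert out[1] == pytest.approx(out[0], rel=0.05)
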