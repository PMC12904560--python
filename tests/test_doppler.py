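import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nvflow as nv
from nvflow import doppler as dop
from nvflow.core import wrap_phase


def _volume_from_phase_ramp(meta, delta, nz=8, nx=16, nt=3, amp=1.0):
    """Uniform per-A-scan phase ramp of ``delta`` radians."""
    phase = delta * np.arange(nx)[None, :, None]
    vals = amp * np.exp(1j * np.broadcast_to(phase, (nz, nx, nt)))
    return nv.ComplexVolume(values=vals.astype(complex), metadata=meta,
                            layout="zxt")


class TestPhaseDifference:
    def test_constant_phase_field_is_zero(self, meta):
        pd = dop.phase_difference(_volume_from_phase_ramp(meta, 0.0))
        np.testing.assert_allclose(pd.values, 0.0, atol=1e-12)
        assert pd.correction_state == "raw"

    def test_uniform_ramp_recovered(self, meta):
        pd = dop.phase_difference(_volume_from_phase_ramp(meta, 0.3))
        np.testing.assert_allclose(pd.values[:, :-1], 0.3, atol=1e-12)

    def test_ramp_beyond_pi_wraps(self, meta):
        delta = np.pi + 0.2
        pd = dop.phase_difference(_volume_from_phase_ramp(meta, delta))
        # oracle: argument of the pairwise complex product
        expected = np.angle(np.exp(1j * delta))
        assert expected == pytest.approx(-(np.pi - 0.2))
        np.testing.assert_allclose(pd.values[:, :-1], expected, atol=1e-12)

    def test_magnitude_only_rejected(self, meta):
        vol = nv.ComplexVolume(values=np.ones((4, 8, 2)), metadata=meta,
                               layout="zxt", magnitude_only=True)
        with pytest.raises(ValueError, match="magnitude-only"):
            dop.phase_difference(vol)

    @given(st.integers(0, 2**31 - 1))
    def test_wrap_safety(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((6, 10, 2)) + 1j * rng.standard_normal((6, 10, 2))
        vol = nv.ComplexVolume(values=vals, metadata=nv.ScanMetadata(),
                               layout="zxt")
        pd = dop.phase_difference(vol)
        assert np.all(pd.values >= -np.pi) and np.all(pd.values < np.pi)


class TestBulkCorrection:
    def test_galvo_ramp_removed_from_static_tissue(self, clean_dyc):
        _, vol, truth, _ = clean_dyc
        pd = dop.bulk_correction(dop.phase_difference(vol), truth.rpe_mask)
        # at the RPE depth the ramp (and that depth's bias) cancels exactly
        sel = truth.rpe_mask.copy()
        sel[:, -1] = False
        resid = pd.values[sel, :]
        assert np.abs(dop.circular_mean(resid.ravel())) < 1e-3
        assert pd.correction_state == "bulk_corrected"

    def test_zero_mean_rpe_unchanged(self, meta):
        pd0 = dop.phase_difference(_volume_from_phase_ramp(meta, 0.0))
        rpe = np.zeros((8, 16), bool)
        rpe[4] = True
        pd1 = dop.bulk_correction(pd0, rpe)
        np.testing.assert_allclose(pd1.values, pd0.values, atol=1e-12)

    def test_uniform_weights_reduce_to_plain_circular_mean(self):
        phases = np.array([0.2, 0.3, -0.1, 0.25])
        assert dop.circular_mean(phases) == pytest.approx(
            dop.circular_mean(phases, np.full(4, 3.7)))

    def test_empty_rpe_names_bscan(self, meta):
        pd = dop.phase_difference(_volume_from_phase_ramp(meta, 0.1))
        with pytest.raises(ValueError, match="t=0"):
            dop.bulk_correction(pd, np.zeros((8, 16), bool))


class TestLocalBackgroundCorrection:
    @pytest.fixture()
    def corrected(self, clean_dyc):
        _, vol, truth, dphi = clean_dyc
        vt = truth.vessels[0]
        roi = dop.VesselROI(mask=vt.occupancy, alpha=vt.alpha, label="v1")
        pd = dop.bulk_correction(dop.phase_difference(vol), truth.rpe_mask)
        return pd, dop.local_background_correction(pd, roi), roi, vt, dphi

    def test_depth_varying_bias_removed_exactly(self, corrected):
        _, pdc, roi, vt, dphi = corrected
        sel = dop.pair_interior(vt.core)
        np.testing.assert_allclose(pdc.values[sel, :], dphi, atol=1e-6)
        assert pdc.correction_state == "fully_corrected"

    def test_idempotent_at_zero_residual_bias(self, meta):
        pd0 = dop.phase_difference(_volume_from_phase_ramp(meta, 0.0,
                                                           nz=20, nx=60))
        pd0 = pd0._advance(pd0.values, "bulk_corrected")
        mask = np.zeros((20, 60), bool)
        mask[8:12, 28:33] = True
        roi = dop.VesselROI(mask=mask)
        once = dop.local_background_correction(pd0, roi)
        twice = dop.local_background_correction(once, roi)
        sel = dop.pair_interior(mask)
        assert np.max(np.abs(wrap_phase(twice.values[sel] - once.values[sel]))) < 1e-9

    def test_constant_bias_subtracted(self, meta):
        pd0 = dop.phase_difference(_volume_from_phase_ramp(meta, 0.0,
                                                           nz=20, nx=60))
        biased = pd0._advance(wrap_phase(pd0.values + 0.17), "bulk_corrected")
        mask = np.zeros((20, 60), bool)
        mask[8:12, 28:33] = True
        roi = dop.VesselROI(mask=mask)
        out = dop.local_background_correction(biased, roi)
        sel = dop.pair_interior(mask)
        np.testing.assert_allclose(out.values[sel, :], 0.0, atol=1e-12)

    def test_flank_consumed_raises(self, meta):
        pd0 = dop.phase_difference(_volume_from_phase_ramp(meta, 0.0,
                                                           nz=10, nx=12))
        pd0 = pd0._advance(pd0.values, "bulk_corrected")
        mask = np.zeros((10, 12), bool)
        mask[4:6, 1:11] = True  # dilated mask spans almost every column
        roi = dop.VesselROI(mask=mask)
        with pytest.raises(ValueError, match="consumed"):
            dop.local_background_correction(pd0, roi)


class TestAverageRepeats:
    def _pd(self, values, layout="zxyr"):
        values = np.asarray(values, float)
        return dop.PhaseDiffMap(values=values, weights=np.ones_like(values),
                                layout=layout, correction_state="fully_corrected")

    def test_identical_repeats_unchanged(self):
        vals = np.full((3, 4, 2, 5), 0.1)
        out = dop.average_repeats(self._pd(vals))
        np.testing.assert_allclose(out.values, 0.1, atol=1e-12)

    def test_wrap_straddling_values_average_to_pi(self):
        vals = np.zeros((1, 1, 1, 2))
        vals[..., 0] = np.pi - 0.1
        vals[..., 1] = -np.pi + 0.1
        out = dop.average_repeats(self._pd(vals))
        # complex-vector mean lands on +/- pi, not on 0
        assert abs(abs(out.values[0, 0, 0]) - np.pi) < 1e-9

    def test_single_repeat_warns(self):
        pd = self._pd(np.zeros((3, 4, 2)), layout="zxy")
        with pytest.warns(RuntimeWarning):
            out = dop.average_repeats(pd)
        assert out is pd


class TestVelocityConversion:
    def test_zero_phase_zero_velocity(self, meta):
        pd = dop.PhaseDiffMap(values=np.zeros((2, 3, 2)),
                              weights=np.ones((2, 3, 2)), layout="zxt",
                              correction_state="fully_corrected")
        field = dop.axial_velocity(pd, meta)
        np.testing.assert_array_equal(field.values, 0.0)

    def test_nyquist_phase_gives_closed_form_speed(self, meta):
        # dphi just below pi (pi itself wraps to -pi in the half-open range)
        phi = np.pi - 1e-12
        pd = dop.PhaseDiffMap(values=np.full((1, 2, 1), phi),
                              weights=np.ones((1, 2, 1)), layout="zxt",
                              correction_state="fully_corrected")
        v = dop.axial_velocity(pd, meta).values[0, 0, 0]
        expected_mm_s = 840e-9 / (4 * 1.35 * (1 / 83_000)) * 1e3
        assert v == pytest.approx(expected_mm_s, rel=1e-9)

    def test_linearity(self, meta):
        pd1 = dop.PhaseDiffMap(values=np.full((1, 2, 1), 0.3),
                               weights=np.ones((1, 2, 1)), layout="zxt",
                               correction_state="fully_corrected")
        pd2 = dop.PhaseDiffMap(values=np.full((1, 2, 1), 0.6),
                               weights=np.ones((1, 2, 1)), layout="zxt",
                               correction_state="fully_corrected")
        assert dop.axial_velocity(pd2, meta).values[0, 0, 0] == pytest.approx(
            2 * dop.axial_velocity(pd1, meta).values[0, 0, 0])

    def test_requires_fully_corrected(self, meta):
        pd = dop.PhaseDiffMap(values=np.zeros((2, 3, 2)),
                              weights=np.ones((2, 3, 2)), layout="zxt")
        with pytest.raises(ValueError, match="fully corrected"):
            dop.axial_velocity(pd, meta)

    def test_longitudinal_projection(self):
        assert dop.longitudinal_velocity(1.0, 0.0) == pytest.approx(1.0)
        assert dop.longitudinal_velocity(1.0, 1.07) == pytest.approx(
            1.0 / np.cos(1.07))
        with pytest.raises(ValueError, match="perpendicular"):
            dop.longitudinal_velocity(1.0, 1.48)  # at/above pi/2 - margin


class TestRoiMeanVelocity:
    def _field(self, values, meta):
        values = np.asarray(values, float)
        return dop.VelocityField(values=values, weights=np.ones_like(values),
                                 layout="zxt", correction_state="fully_corrected")

    def test_uniform_velocity(self, meta):
        field = self._field(np.full((6, 8, 3), 1.4), meta)
        mask = np.zeros((6, 8), bool)
        mask[2:5, 2:6] = True
        trace = dop.roi_mean_velocity(field, dop.VesselROI(mask=mask), meta)
        np.testing.assert_allclose(trace.values, 1.4)
        np.testing.assert_allclose(np.diff(trace.times), meta.interscan_time)

    def test_opposing_halves_cancel(self, meta):
        vals = np.zeros((6, 8, 2))
        vals[:3] = 2.0   # top half +v, bottom half -v (split along depth)
        vals[3:] = -2.0
        mask = np.zeros((6, 8), bool)
        mask[1:5, 2:6] = True
        field = self._field(vals, meta)
        trace = dop.roi_mean_velocity(field, dop.VesselROI(mask=mask), meta)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)

    def test_parabolic_profile_mean_matches_discrete_sum(self, meta):
        nz, nx = 20, 24
        z = np.arange(nz)
        profile = 3.0 * np.maximum(1 - ((z - 10) / 6.0) ** 2, 0)
        vals = np.broadcast_to(profile[:, None, None], (nz, nx, 2)).copy()
        mask = np.zeros((nz, nx), bool)
        mask[4:17, 5:15] = True
        field = self._field(vals, meta)
        trace = dop.roi_mean_velocity(field, dop.VesselROI(mask=mask), meta)
        sel = dop.pair_interior(mask)
        expected = sum(profile[i] for i, j in zip(*np.nonzero(sel))) / sel.sum()
        assert trace.values[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_roi_yields_nan(self, meta):
        field = self._field(np.ones((4, 6, 2)), meta)
        field.weights[:] = 0.0
        mask = np.zeros((4, 6), bool)
        mask[1, 2] = True
        trace = dop.roi_mean_velocity(field, dop.VesselROI(mask=mask), meta)
        assert np.isnan(trace.values).all()


def test_recovery_with_noise_galvo_and_depth_bias(noisy_dyc, meta):
    """ROI-mean longitudinal velocity within 5% at 20 dB SNR; the same
    corrections are exact (0.1%) on the clean twin scene."""
    scene, vol, truth, dphi = noisy_dyc
    vt = truth.vessels[0]
    roi = dop.VesselROI(mask=vt.occupancy, alpha=vt.alpha)
    pd = dop.local_background_correction(
        dop.bulk_correction(dop.phase_difference(vol), truth.rpe_mask), roi)
    field = dop.longitudinal_velocity(dop.axial_velocity(pd, meta), vt.alpha)
    core_roi = dop.VesselROI(mask=vt.core, alpha=vt.alpha)
    trace = dop.roi_mean_velocity(field, core_roi, meta)
    v_true = vt.v_long[0] * 1e3
    assert abs(np.nanmean(trace.values) - v_true) < 0.05 * abs(v_true)


def test_recovery_exact_at_zero_noise(clean_dyc, meta):
    scene, vol, truth, dphi = clean_dyc
    vt = truth.vessels[0]
    roi = dop.VesselROI(mask=vt.occupancy, alpha=vt.alpha)
    pd = dop.local_background_correction(
        dop.bulk_correction(dop.phase_difference(vol), truth.rpe_mask), roi)
    field = dop.longitudinal_velocity(dop.axial_velocity(pd, meta), vt.alpha)
    trace = dop.roi_mean_velocity(field, dop.VesselROI(mask=vt.core,
                                                       alpha=vt.alpha), meta)
    v_true = vt.v_long[0] * 1e3
    assert abs(np.nanmean(trace.values) - v_true) < 1e-3 * abs(v_true)
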