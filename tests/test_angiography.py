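import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nvflow as nv
from nvflow import angiography as ang


def naive_complex_subtraction(repeats):
    """Loop oracle: per adjacent pair, remove the intensity-weighted bulk
    phase offset, then average the moduli of the differences."""
    out = np.zeros(repeats.shape[1:])
    for k in range(repeats.shape[0] - 1):
        a, b = repeats[k], repeats[k + 1]
        acc = 0.0 + 0.0j
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                acc += np.conj(a[i, j]) * b[i, j]
        phi = np.angle(acc) if acc != 0 else 0.0
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                out[i, j] += abs(b[i, j] * np.exp(-1j * phi) - a[i, j])
    return out / (repeats.shape[0] - 1)


def naive_uniform_filter(img, k):
    """Loop oracle for the edge-replicated mean filter; for even kernels the
    footprint extends one pixel further towards smaller indices."""
    lo = k // 2
    hi = k - lo - 1
    out = np.zeros_like(img, dtype=float)
    nz, nx = img.shape
    for i in range(nz):
        for j in range(nx):
            acc = 0.0
            for di in range(-lo, hi + 1):
                for dj in range(-lo, hi + 1):
                    ii = min(max(i + di, 0), nz - 1)
                    jj = min(max(j + dj, 0), nx - 1)
                    acc += img[ii, jj]
            out[i, j] = acc / k**2
    return out


class TestFlatten:
    def test_flat_scene_zero_shifts(self, clean_dyc):
        _, vol, _, _ = clean_dyc
        flat, shifts = ang.flatten_by_rpe(vol)
        assert np.all(shifts == 0)
        np.testing.assert_array_equal(flat.values, vol.values)

    def test_tilt_ramp_recovered(self, meta):
        scene = nv.SyntheticScene(metadata=meta, dims=(48, 64, 4),
                                  rpe_depth_index=30, vessels=[],
                                  noise_sigma=0.05, seed=8, rpe_tilt_px=3.0)
        vol, truth = nv.simulate_dyc_series(scene)
        _, shifts = ang.flatten_by_rpe(vol)
        # recovered shifts undo the injected per-column tilt (up to a global
        # constant); detection may round differently right at a ramp step
        undo = shifts + truth.rpe_tilt_shifts
        mode = np.bincount(undo - undo.min()).argmax() + undo.min()
        assert np.mean(undo == mode) >= 0.95
        assert np.max(np.abs(undo - mode)) <= 1

    def test_pure_noise_raises(self, meta):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((48, 64, 4)) + 1j * rng.standard_normal((48, 64, 4))
        vol = nv.ComplexVolume(values=vals, metadata=meta, layout="zxt")
        with pytest.raises(ValueError, match="no detectable RPE band"):
            ang.flatten_by_rpe(vol)


class TestComplexSubtraction:
    def test_identical_repeats_zero(self):
        rng = np.random.default_rng(1)
        b = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        reps = np.stack([b] * 5)
        np.testing.assert_allclose(ang.complex_subtraction_angiogram(reps),
                                   0.0, atol=1e-12)

    def test_pi_flip_gives_twice_amplitude(self):
        base = np.full((16, 16), 3.0 + 0.0j)
        flipped = base.copy()
        flipped[5, 7] = -base[5, 7]  # phase flip by pi at amplitude A = 3
        out = ang.complex_subtraction_angiogram(np.stack([base, flipped]))
        # one flipped voxel among 256: bulk offset is negligible
        assert out[5, 7] == pytest.approx(6.0, rel=1e-2)
        mask = np.ones_like(out, bool)
        mask[5, 7] = False
        assert np.all(out[mask] < 0.1)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        reps = rng.standard_normal((5, 12, 10)) + 1j * rng.standard_normal((5, 12, 10))
        np.testing.assert_allclose(ang.complex_subtraction_angiogram(reps),
                                   naive_complex_subtraction(reps), rtol=1e-12)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            ang.complex_subtraction_angiogram(np.zeros((1, 4, 4), complex))

    def test_static_scene_angiogram_null(self, meta):
        scene = nv.SyntheticScene(metadata=meta, dims=(24, 32, 8),
                                  rpe_depth_index=18, vessels=[],
                                  noise_sigma=0.0, seed=4)
        vol, _ = nv.simulate_angio_volume(scene)
        angio = ang.angiogram_volume(vol)
        np.testing.assert_allclose(angio.values, 0.0, atol=1e-12)


class TestSmooth:
    @pytest.mark.parametrize("kernel", [3, 10])
    def test_constant_preserved(self, kernel):
        a = ang.AngiogramVolume(values=np.full((16, 16), 2.5), n_repeats=5)
        np.testing.assert_allclose(ang.smooth(a, kernel).values, 2.5)

    def test_impulse_response_3x3(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = ang.smooth(ang.AngiogramVolume(values=img, n_repeats=5), 3).values
        np.testing.assert_allclose(out[6:9, 6:9], 1 / 9)
        assert out.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("kernel", [3, 10])
    def test_matches_loop_oracle(self, kernel):
        rng = np.random.default_rng(3)
        img = rng.random((16, 16))
        out = ang.smooth(ang.AngiogramVolume(values=img, n_repeats=5), kernel)
        np.testing.assert_allclose(out.values, naive_uniform_filter(img, kernel),
                                   rtol=1e-12)

    def test_kernel_must_fit(self):
        with pytest.raises(ValueError):
            ang.smooth(ang.AngiogramVolume(values=np.ones((4, 4)), n_repeats=5), 10)


class TestReferenceAndMask:
    def test_all_zero_reference(self):
        a = ang.AngiogramVolume(values=np.zeros((8, 8, 3)), n_repeats=5)
        assert ang.reference_value(a) == 0.0

    def test_single_uniform_row(self):
        vals = np.zeros((8, 10, 3))
        vals[4, :, 1] = 7.0  # one depth row of one B-scan uniformly c
        a = ang.AngiogramVolume(values=vals, n_repeats=5)
        assert ang.reference_value(a) == pytest.approx(7.0)

    def test_reference_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.random((9, 11, 4))
        best = -np.inf
        for b in range(4):
            for z in range(9):
                best = max(best, vals[z, :, b].mean())
        a = ang.AngiogramVolume(values=vals, n_repeats=5)
        assert ang.reference_value(a) == pytest.approx(best, rel=1e-12)

    def test_binarize_includes_threshold_pixels(self):
        vals = np.array([[0.9, 0.89], [0.91, 0.0]])
        mask = ang.binarize(ang.AngiogramVolume(values=vals, n_repeats=5),
                            reference=10.0, fraction=0.09)
        np.testing.assert_array_equal(mask.values,
                                      [[True, False], [True, False]])

    def test_binarize_validation(self):
        a = ang.AngiogramVolume(values=np.ones((4, 4)), n_repeats=5)
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                ang.binarize(a, reference=1.0, fraction=frac)
        with pytest.raises(ValueError):
            ang.binarize(a, reference=0.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.45), st.floats(0.46, 0.95))
    def test_threshold_monotonicity(self, seed, lo, hi):
        rng = np.random.default_rng(seed)
        vals = rng.random((12, 12))
        a = ang.AngiogramVolume(values=vals, n_repeats=5)
        mask_lo = ang.binarize(a, reference=1.0, fraction=lo).values
        mask_hi = ang.binarize(a, reference=1.0, fraction=hi).values
        assert np.all(mask_lo | ~mask_hi)  # mask(hi) subset of mask(lo)


def test_contrast_response_in_vessel_mask(meta):
    """Angiogram intensity inside the vessel mask peaks with the bolus and
    stays above the pre-injection baseline afterwards."""
    means = {}
    for tag, enh in (("pre", 1.0), ("peak", 4.0), ("late", 2.0)):
        vessel = nv.straight_vessel(metadata=meta, dims=(32, 48, 24),
                                    angle_alpha=0.3, azimuth=0.5, radius=12e-6,
                                    speed_profile=1.5e-3,
                                    backscatter_baseline=0.8 * enh)
        scene = nv.SyntheticScene(metadata=meta, dims=(32, 48, 24),
                                  rpe_depth_index=26, vessels=[vessel],
                                  noise_sigma=0.1, seed=6)
        vol, truth = nv.simulate_angio_volume(scene)
        angio = ang.angiogram_volume(vol)
        means[tag] = angio.values[truth.vessels[0].occupancy].mean()
    assert means["peak"] > means["pre"]
    assert means["late"] > means["pre"]


def test_mask_covers_vessel_core_at_default_threshold(angio_tube):
    scene, vol, truth = angio_tube
    angio = ang.angiogram_volume(vol)
    ref = ang.reference_value(ang.smooth(angio, 10))
    mask = ang.binarize(ang.smooth(angio, 3), ref, fraction=0.09)
    core = truth.vessels[0].core
    assert mask.values[core].mean() > 0.9
    # avascular retina above the RPE (clear of the vessel) stays unmasked
    background = truth.vessels[0].coverage == 0
    background[scene.rpe_depth_index - 4:] = False
    assert mask.values[background].mean() < 0.1
    # the perfused choroid band itself is (correctly) detected as flow
    assert mask.values[truth.choroid_mask].mean() > 0.5
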