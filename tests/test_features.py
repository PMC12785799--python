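import numpy as np
import pytest
import pywt

from ecgfusion.features import (
    DEFAULT_SCALES,
    GrayImage,
    Keypoint,
    assign_orientation,
    build_scale_space,
    cwt_scalogram,
    density_map,
    detect_keypoints,
    finalize_sift_channel,
    fuse,
    minmax01,
    resize_image,
    sampled_wavelet,
    to_gray,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def cwt_oracle(x, wavelet_name, scales):
    """Direct time-domain convolution, one dot product per (scale, shift)."""
    wav = pywt.ContinuousWavelet(wavelet_name)
    psi, grid = wav.wavefun(level=12)
    ub = wav.upper_bound
    out = np.empty((len(scales), len(x)))
    for i, s in enumerate(scales):
        half = int(np.ceil(s * ub))
        m = np.arange(-half, half + 1)
        w = np.interp(m / s, grid, psi, left=0.0, right=0.0) / np.sqrt(s)
        xp = np.pad(x, half, mode="symmetric")
        for u in range(len(x)):
            out[i, u] = float(np.dot(xp[u : u + len(w)], w))
    return np.abs(out)


def dog_extrema_scan(dog):
    """Exhaustive python-loop scan for strict 26-neighborhood extrema."""
    found = []
    L, H, W = dog.shape
    for l in range(1, L - 1):
        for r in range(1, H - 1):
            for c in range(1, W - 1):
                v = dog[l, r, c]
                patch = dog[l - 1 : l + 2, r - 1 : r + 2, c - 1 : c + 2]
                others = np.delete(patch.ravel(), 13)
                if np.all(v > others) or np.all(v < others):
                    found.append((l, r, c, v))
    return found


def blob_image(h=64, w=64, cy=30.0, cx=40.0, sigma=3.0, amp=255.0):
    yy, xx = np.mgrid[:h, :w]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# CWT
# ---------------------------------------------------------------------------


class TestCwtScalogram:
    def test_zero_segment_gives_zero_scalogram(self):
        sc = cwt_scalogram(np.zeros(82), "morl")
        assert sc.matrix.shape == (64, 82)
        assert np.all(sc.matrix == 0)

    @pytest.mark.parametrize("wavelet", ["morl", "mexh"])
    def test_matches_direct_convolution_oracle(self, wavelet, rng):
        scales = np.array([1, 2, 5, 13, 31, 64])
        for _ in range(3):
            x = rng.standard_normal(82)
            prod = cwt_scalogram(x, wavelet, scales).matrix
            orac = cwt_oracle(x, wavelet, scales)
            denom = np.maximum(np.abs(orac), 1e-12)
            assert np.max(np.abs(prod - orac) / denom) < 1e-6

    @pytest.mark.parametrize("wavelet,freq", [("morl", 5.0), ("mexh", 2.0)])
    def test_sinusoid_peaks_at_center_frequency_scale(self, wavelet, freq):
        fs = 128.0
        t = np.arange(256) / fs
        x = np.sin(2 * np.pi * freq * t)
        sc = cwt_scalogram(x, wavelet)
        best = sc.scales[np.argmax(sc.matrix.mean(axis=1))]
        expected = pywt.central_frequency(wavelet) * fs / freq
        assert abs(best - expected) <= 1.0 + 0.5  # scale grid is integer

    def test_linearity_in_amplitude(self, beat_segment):
        x = beat_segment.samples
        a = cwt_scalogram(x, "mexh").matrix
        b = cwt_scalogram(3.0 * x, "mexh").matrix
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9, atol=1e-12)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            cwt_scalogram(np.ones(82), "db6")


# ---------------------------------------------------------------------------
# Gray conversion / resize
# ---------------------------------------------------------------------------


class TestGrayAndResize:
    def test_constant_matrix_maps_to_zero(self):
        g = to_gray(np.full((4, 5), 7.0))
        assert np.all(g.matrix == 0)

    def test_linear_map_values(self):
        g = to_gray(np.array([[2.0, 3.0], [4.0, 3.0]]))
        assert g.matrix[0, 0] == 0
        assert g.matrix[1, 0] == 255
        assert g.matrix[0, 1] == pytest.approx(127.5)

    def test_range_bounded_for_random_input(self, rng):
        g = to_gray(rng.standard_normal((16, 16)))
        assert g.matrix.min() >= 0 and g.matrix.max() <= 255

    def test_resize_to_own_size_is_identity(self, rng):
        img = rng.random((7, 9))
        np.testing.assert_allclose(resize_image(img, 7, 9), img, atol=1e-9)

    def test_resize_constant_stays_constant(self):
        out = resize_image(np.full((3, 3), 2.5), 10, 12)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_bilinear_2x2_to_4x4_oracle(self):
        """Hand-computed bilinear weights on the half-pixel-aligned grid."""
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = resize_image(img, 4, 4)
        # target pixel centers map to source coords (i + 0.5)/2 - 0.5,
        # i.e. [-0.25, 0.25, 0.75, 1.25], edge-clamped to [0, 1]
        coords = np.clip((np.arange(4) + 0.5) / 2 - 0.5, 0.0, 1.0)
        expected = np.empty((4, 4))
        for i, ry in enumerate(coords):
            for j, rx in enumerate(coords):
                y0, x0 = int(np.floor(ry)), int(np.floor(rx))
                y1, x1 = min(y0 + 1, 1), min(x0 + 1, 1)
                fy, fx = ry - y0, rx - x0
                expected[i, j] = (
                    img[y0, x0] * (1 - fy) * (1 - fx)
                    + img[y0, x1] * (1 - fy) * fx
                    + img[y1, x0] * fy * (1 - fx)
                    + img[y1, x1] * fy * fx
                )
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resize_image(np.ones((4, 4)), 0, 4)


# ---------------------------------------------------------------------------
# Scale space and keypoints
# ---------------------------------------------------------------------------


class TestScaleSpace:
    def test_dog_stack_length_per_octave(self):
        ss = build_scale_space(np.random.default_rng(0).random((32, 32)) * 255, intervals=3)
        for g, d in zip(ss.octaves, ss.dog):
            assert d.shape[0] == g.shape[0] - 1 == 3 + 2

    def test_spatial_size_halves_per_octave(self):
        ss = build_scale_space(np.zeros((64, 64)), intervals=3)
        sizes = [o.shape[1] for o in ss.octaves]
        assert sizes == sorted(sizes, reverse=True)
        for a, b in zip(sizes, sizes[1:]):
            assert b == a // 2

    def test_identical_levels_give_zero_dog(self):
        img = np.random.default_rng(1).random((16, 16)) * 255
        ss = build_scale_space(img)
        manual = ss.octaves[0][2] - ss.octaves[0][1]
        np.testing.assert_allclose(ss.dog[0][1], manual, atol=1e-12)
        np.testing.assert_allclose(manual - manual, 0, atol=0)

    def test_gaussian_blur_of_delta_matches_analytic_kernel(self):
        from scipy.ndimage import gaussian_filter

        delta = np.zeros((33, 33))
        delta[16, 16] = 1.0
        sigma = 1.6
        blurred = gaussian_filter(delta, sigma)
        yy, xx = np.mgrid[-16:17, -16:17]
        analytic = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        analytic /= analytic.sum()
        # default kernel truncation (4 sigma) bounds the discrepancy
        assert np.max(np.abs(blurred - analytic)) < 1e-5
        exact = gaussian_filter(delta, sigma, truncate=10.0)
        assert np.max(np.abs(exact - analytic)) < 1e-9

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="small"):
            build_scale_space(np.zeros((4, 4)))


class TestDetectKeypoints:
    def test_uniform_image_has_no_keypoints(self):
        assert detect_keypoints(np.full((64, 64), 80.0)) == []

    def test_blob_detected_near_center_and_agrees_with_scan(self):
        img = blob_image()
        kps = detect_keypoints(img)
        assert kps, "no keypoint found on a bright blob"
        d = min(np.hypot(k.x - 40.0, k.y - 30.0) for k in kps)
        assert d <= 1.5
        # oracle: exhaustive 26-neighbor scan of the same DoG stack
        ss = build_scale_space(img)
        best = None
        for o, dog in enumerate(ss.dog):
            for l, r, c, v in dog_extrema_scan(dog):
                pos = (r * 2.0**o, c * 2.0**o)
                dd = np.hypot(pos[0] - 30.0, pos[1] - 40.0)
                if best is None or dd < best:
                    best = dd
        assert best is not None and best <= 1.5

    def test_low_amplitude_blob_rejected_by_contrast(self):
        # refined |D| scales linearly with amplitude; far below 0.04 -> none
        img = blob_image(amp=2.0)  # 2/255 intensity
        assert detect_keypoints(img, contrast_thr=0.04) == []

    def test_thresholds_act_monotonically(self):
        img = blob_image() + blob_image(cy=50.0, cx=12.0, sigma=2.0, amp=120.0)

        def keyset(**kw):
            return {(round(k.x, 2), round(k.y, 2), round(k.sigma, 2))
                    for k in detect_keypoints(img, **kw)}

        assert keyset(contrast_thr=0.04) <= keyset(contrast_thr=0.01)
        assert keyset(edge_thr=10) <= keyset(edge_thr=30)

    def test_keypoint_count_invariant_to_constant_offset(self):
        img = blob_image(amp=150.0)
        base = detect_keypoints(img)
        shifted = detect_keypoints(img + 50.0)
        assert len(base) == len(shifted)


class TestAssignOrientation:
    @staticmethod
    def _ramp_space(theta_deg):
        """Scale space of an intensity ramp with gradient direction theta."""
        yy, xx = np.mgrid[:64, :64].astype(float)
        th = np.radians(theta_deg)
        img = np.cos(th) * xx + np.sin(th) * yy
        img = 255 * minmax01(img)
        return build_scale_space(img)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 90.0])
    def test_uniform_gradient_direction_recovered(self, theta):
        ss = self._ramp_space(theta)
        kp = Keypoint(x=32.0, y=32.0, sigma=1.6, response=1.0)
        out = assign_orientation(kp, ss)
        diff = min(abs(out[0].orientation - theta) % 360,
                   360 - abs(out[0].orientation - theta) % 360)
        assert diff <= 10.0

    def test_rotating_neighborhood_rotates_orientation(self):
        a = assign_orientation(Keypoint(32, 32, 1.6, 1.0), self._ramp_space(10.0))
        b = assign_orientation(Keypoint(32, 32, 1.6, 1.0), self._ramp_space(100.0))
        delta = (b[0].orientation - a[0].orientation) % 360
        assert abs(delta - 90.0) <= 10.0

    def test_flat_neighborhood_keeps_single_zero_orientation(self):
        ss = build_scale_space(np.full((64, 64), 128.0))
        out = assign_orientation(Keypoint(32, 32, 1.6, 1.0), ss)
        assert len(out) == 1 and out[0].orientation == 0.0


# ---------------------------------------------------------------------------
# Density map and fusion
# ---------------------------------------------------------------------------


class TestDensityMap:
    def test_empty_list_gives_zero_map(self):
        dm = density_map([])
        assert dm.counts.shape == (5, 128)
        assert dm.n_keypoints == 0 and np.all(dm.counts == 0)

    def test_counts_conserved(self, rng):
        kps = [Keypoint(float(x), float(y), 1.0, 1.0)
               for x, y in rng.random((3, 2)) * 127]
        dm = density_map(kps)
        assert dm.counts.sum() == 3 == dm.n_keypoints

    def test_coordinate_scaling_rule(self):
        dm = density_map([Keypoint(64.0, 64.0, 1.0, 1.0)], src_h=128, src_w=128)
        assert dm.counts[2, 64] == 1

    def test_disk_mode_stamps_circle(self):
        dm = density_map([Keypoint(64.0, 64.0, 2.0, 1.0)], mode="disk")
        assert dm.counts.sum() > 1


class TestFinalizeSiftChannel:
    def test_zero_map_stays_zero(self):
        from ecgfusion.features import DensityMap

        ch = finalize_sift_channel(DensityMap(np.zeros((5, 128)), 0))
        assert ch.shape == (128, 128) and np.all(ch == 0)

    def test_blur_preserves_unit_mass_interior(self):
        from scipy.ndimage import gaussian_filter

        m = np.zeros((5, 128))
        m[2, 64] = 1.0
        blurred = gaussian_filter(m, sigma=1.0, truncate=1.0, mode="reflect")
        assert blurred.sum() == pytest.approx(1.0, abs=1e-12)

    def test_max_is_one_for_nonzero_map(self):
        from ecgfusion.features import DensityMap

        m = np.zeros((5, 128))
        m[1, 10] = 3.0
        ch = finalize_sift_channel(DensityMap(m, 3))
        assert ch.max() == pytest.approx(1.0)


class TestFuse:
    def test_all_zero_segment_gives_all_zero_image(self):
        img = fuse(np.zeros(82))
        assert img.channels.shape == (128, 128, 3)
        assert np.all(img.channels == 0)

    def test_shape_and_range_contract(self, beat_segment):
        img = fuse(beat_segment)
        assert img.channels.shape == (128, 128, 3)
        assert img.channels.min() >= 0.0 and img.channels.max() <= 1.0

    def test_deterministic(self, beat_segment):
        a = fuse(beat_segment).channels
        b = fuse(beat_segment).channels
        assert np.array_equal(a, b)

    def test_channel_roles_order(self, beat_segment):
        img = fuse(beat_segment)
        assert img.channel_roles == ("mexh-scalogram", "morl-scalogram", "sift-density")
        sc = cwt_scalogram(beat_segment.samples, "mexh", DEFAULT_SCALES)
        expected = resize_image(minmax01(sc.matrix), 128, 128)
        np.testing.assert_allclose(img.channels[..., 0], np.clip(expected, 0, 1), atol=1e-12)
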