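"""Forward-simulator contracts: determinism, energy, statistics, geometry."""

import numpy as np
import pytest

import specklekin as sk
from specklekin.synthetic import point_object


def _contrast_of_speckle(seed, n_bands, shape=(64, 64)):
    """std/mean of a pure-speckle (no halo) impulse response."""
    med = sk.make_medium(seed, shape, grain_size=4, halo_sigma=8,
                         diffuse_fraction=0.0, n_bands=n_bands)
    resp = med.band_mean_response((shape[0] // 2, shape[1] // 2))
    return float(resp.std() / resp.mean())


class TestMediumContracts:
    def test_reproducible_impulse_responses(self):
        a = sk.make_medium(3, (64, 64), 4, 8, 0.5, 2)
        b = sk.make_medium(3, (64, 64), 4, 8, 0.5, 2)
        for src, band in [((10, 20), 0), ((10, 20), 1), ((63, 0), 0)]:
            np.testing.assert_array_equal(
                sk.impulse_response(a, src, band), sk.impulse_response(b, src, band)
            )

    @pytest.mark.parametrize("source", [(0, 0), (32, 32), (63, 63), (5, 60)])
    def test_unit_energy_everywhere(self, small_medium, source):
        resp = sk.impulse_response(small_medium, source)
        assert resp.min() >= 0
        assert abs(resp.sum() - 1.0) < 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sk.make_medium(1, (0, 64))
        with pytest.raises(ValueError):
            sk.make_medium(1, (64, 64), grain_size=1.0)
        with pytest.raises(ValueError):
            sk.make_medium(1, (64, 64), diffuse_fraction=1.0)
        with pytest.raises(ValueError):
            sk.make_medium(1, (64, 64), n_bands=0)

    def test_out_of_grid_source_rejected(self, small_medium):
        with pytest.raises(ValueError):
            sk.impulse_response(small_medium, (64, 0))
        with pytest.raises(ValueError):
            sk.impulse_response(small_medium, (0, 0), band=1)


class TestSpeckleStatistics:
    def test_contrast_decreases_with_bands(self):
        """Broadband (multi-band) speckle has monotonically lower contrast."""
        means = []
        for nb in (1, 2, 4, 8):
            means.append(np.mean([_contrast_of_speckle(s, nb) for s in range(20)]))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_contrast_scales_inverse_sqrt_bands(self):
        c1 = np.mean([_contrast_of_speckle(s, 1) for s in range(20)])
        c8 = np.mean([_contrast_of_speckle(s, 8) for s in range(20)])
        assert abs(c8 / c1 - 1 / np.sqrt(8)) < 0.05

    def test_distant_sources_uncorrelated(self):
        """Speckle parts of well-separated sources are independent."""
        rs = []
        for seed in range(20):
            med = sk.make_medium(seed, (256, 256), 4, 20, 0.0, 1)
            a = med._speckle_part((100, 100), 0).ravel()
            b = med._speckle_part((100, 120), 0).ravel()  # 20 px > 2*grain
            rs.append(abs(np.corrcoef(a, b)[0, 1]))
        assert np.mean(rs) < 0.05

    def test_autocovariance_width_tracks_grain(self):
        """FWHM of the intensity autocovariance approximates grain_size."""
        for grain in (4.0, 8.0):
            med = sk.make_medium(7, (256, 256), grain, 20, 0.0, 1)
            f = med._speckle_part((128, 128), 0)
            f0 = f - f.mean()
            ac = np.fft.fftshift(
                np.fft.ifft2(np.abs(np.fft.fft2(f0)) ** 2).real
            )
            row = ac[128]
            half = row.max() / 2
            above = np.nonzero(row >= half)[0]
            fwhm = above.max() - above.min() + 1
            assert 0.5 * grain <= fwhm <= 1.8 * grain


class TestRendering:
    def test_point_object_reproduces_impulse_response(self, small_medium):
        frame = sk.render_frame(small_medium, point_object())
        # 9x9 mask centred on the 64x64 grid puts its centre pixel at (31, 31)
        resp = small_medium.band_mean_response((31, 31))
        np.testing.assert_allclose(frame, resp, rtol=1e-10)

    def test_incoherent_superposition_is_linear(self, small_medium):
        vals = np.zeros((9, 9))
        vals[2, 2] = 1.0
        vals[6, 7] = 1.0
        two = sk.ObjectMask(vals)
        frame = sk.render_frame(small_medium, two)
        r1 = small_medium.band_mean_response((27 + 2, 27 + 2))
        r2 = small_medium.band_mean_response((27 + 6, 27 + 7))
        np.testing.assert_allclose(frame, r1 + r2, rtol=1e-6)

    def test_envelope_translates_with_object(self, small_medium):
        """The low-pass part of a shifted-object frame shifts by the offset."""
        obj = sk.two_bar_object(bar_width=2, gap=2, bar_height=8, shape=(24, 24))
        f0 = sk.render_frame(small_medium, obj, offset=(0, 0))
        f1 = sk.render_frame(small_medium, obj, offset=(3, 5))
        env0, _ = sk.separate(f0, cutoff=8)
        env1, _ = sk.separate(f1, cutoff=8)
        (dy, dx), _ = sk.displacement_estimate(env0, env1)
        assert (dy, dx) == (3, 5)

    def test_off_grid_object_rejected(self, small_medium):
        obj = sk.two_bar_object(shape=(64, 64))
        with pytest.raises(ValueError):
            sk.render_frame(small_medium, obj, offset=(40, 0))

    def test_sequence_determinism_and_metadata(self, small_medium):
        obj = sk.ObjectMask(np.ones((4, 4)) * 0.5)
        traj = [(0, 0), (1, 0), (1, 1)]
        s1 = sk.render_sequence(small_medium, obj, None, traj, bit_depth=8)
        s2 = sk.render_sequence(small_medium, obj, None, traj, bit_depth=8)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert s1.truth_offsets == traj
        assert len(s1) == 3
        assert s1.frames.max() <= 255 and s1.frames.min() >= 0

    def test_quantization_uses_most_of_range(self, small_medium):
        obj = sk.ObjectMask(np.ones((4, 4)))
        stack = sk.render_sequence(small_medium, obj, None, [(0, 0)], bit_depth=8)
        assert 200 <= stack.frames.max() <= 255

    def test_empty_trajectory_rejected(self, small_medium):
        obj = sk.ObjectMask(np.ones((4, 4)))
        with pytest.raises(ValueError):
            sk.render_sequence(small_medium, obj, None, [])

    def test_object_mask_validation(self):
        with pytest.raises(ValueError):
            sk.ObjectMask(np.array([[0.5, 1.5]]))
        with pytest.raises(ValueError):
            sk.ObjectMask(-np.ones((3, 3)))

    def test_illumination_uniformity_enforced(self, small_medium):
        obj = sk.ObjectMask(np.ones((8, 8)))
        ramp = np.linspace(0.1, 2.0, 64)[:, None] * np.ones((64, 64))
        illum = sk.IlluminationField(ramp)
        with pytest.raises(ValueError):
            sk.render_frame(small_medium, obj, illum)
        flat = sk.IlluminationField(np.ones((64, 64)))
        sk.render_frame(small_medium, obj, flat)  # uniform passes
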