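"""Synthetic scanner: shot physics, dataset assembly, multiband pulses."""

import numpy as np
import pytest

from rsepi_sms import (MotionEvent, MotionModel, Simulator, make_sinc_pulse,
                       multiband_pulse, simulate_contrast, simulate_shot)
from rsepi_sms.caipi import make_fov_shift_scheme, slice_line_phase
from rsepi_sms.fourier import fft2c
from rsepi_sms.scanner import navigator_bounds, segment_bounds

from conftest import make_protocol, nrmse


class TestSamplingGeometry:
    def test_segment_bands_tile_the_readout_axis(self):
        for n_seg in (1, 3, 5, 6):
            bounds = segment_bounds(64, n_seg)
            assert bounds[0][0] == 0 and bounds[-1][1] == 64
            for (a, b), (c, d) in zip(bounds, bounds[1:]):
                assert b == c

    def test_navigator_band_covers_kspace_center(self):
        for n_seg in (1, 2, 3, 5, 7):
            lo, hi = navigator_bounds(64, n_seg)
            assert lo <= 32 < hi


class TestSimulateShot:
    def test_clean_unaccelerated_full_width_shot_is_the_dft(self, phantom32,
                                                            coils32):
        """With no corruption, one full-width segment and no acceleration,
        the shot must equal the discrete Fourier transform of the
        coil-weighted image exactly."""
        p = make_protocol(matrix=32, n_segments=1, r_slice=1, r_pe=1,
                          n_slices=2)
        con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
        scheme = make_fov_shift_scheme([0.0])
        rec = simulate_shot(con[[0]], np.stack([coils32.for_slice(0)]), p,
                            scheme, 0)
        expected = fft2c(con[0][None] * coils32.for_slice(0))
        assert np.allclose(rec.imaging_band, expected, atol=1e-12)

    def test_collapse_equals_sum_of_phased_single_band_shots(self, phantom32,
                                                             coils32):
        """Independent oracle: simulate each slice alone (with its CAIPI
        phase) and sum; must match the multiband shot to 1e-12."""
        p = make_protocol(matrix=32, n_segments=3, r_slice=2, r_pe=2,
                          n_slices=2)
        con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
        sens = np.stack([coils32.for_slice(s) for s in range(2)])
        scheme = make_fov_shift_scheme(phantom32.slice_positions_mm)
        rec = simulate_shot(con[:2], sens, p, scheme, 1)
        # loop-based single-band oracle
        ky = np.arange(0, 32, 2)
        m = np.arange(ky.size)
        lo, hi = segment_bounds(32, 3)[1]
        total = np.zeros((8, ky.size, hi - lo), dtype=complex)
        for j in range(2):
            k = fft2c(con[j][None] * sens[j])
            k = k[:, ky, :] * np.exp(1j * slice_line_phase(scheme, j, m))[None, :, None]
            total += k[:, :, lo:hi]
        assert np.allclose(rec.imaging_band, total, atol=1e-12)

    def test_shot_is_linear_in_the_object(self, phantom32, coils32):
        p = make_protocol(matrix=32, n_segments=3, r_slice=2, r_pe=2,
                          n_slices=2)
        sens = np.stack([coils32.for_slice(s) for s in range(2)])
        scheme = make_fov_shift_scheme(phantom32.slice_positions_mm)
        rng = np.random.default_rng(3)
        im1 = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        im2 = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        a, b = 2.0 - 1.0j, -0.5 + 3.0j
        lhs = simulate_shot(a * im1 + b * im2, sens, p, scheme, 0).imaging_band
        rhs = (a * simulate_shot(im1, sens, p, scheme, 0).imaging_band
               + b * simulate_shot(im2, sens, p, scheme, 0).imaging_band)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_parseval_energy_of_uncollapsed_shot(self, phantom32, coils32):
        """Unnormalized-forward FFT convention: k-space energy of a
        full-width noiseless shot equals N^2 times image energy."""
        p = make_protocol(matrix=32, n_segments=1, r_slice=1, r_pe=1,
                          n_slices=2)
        con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
        scheme = make_fov_shift_scheme([0.0])
        rec = simulate_shot(con[[0]], np.stack([coils32.for_slice(0)]), p,
                            scheme, 0)
        img = con[0][None] * coils32.for_slice(0)
        e_k = (np.abs(rec.imaging_band) ** 2).sum()
        e_img = (np.abs(img) ** 2).sum()
        assert e_k == pytest.approx(32 * 32 * e_img, rel=1e-12)

    def test_segment_index_out_of_range(self, phantom32, coils32):
        p = make_protocol(matrix=32, n_segments=3, n_slices=2)
        con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
        sens = np.stack([coils32.for_slice(s) for s in range(2)])
        scheme = make_fov_shift_scheme(phantom32.slice_positions_mm)
        with pytest.raises(ValueError):
            simulate_shot(con[:2], sens, p, scheme, 3)

    def test_noise_standard_deviation_calibrated(self, phantom32, coils32):
        """Empirical per-channel noise std across background samples within
        5% of the requested sigma."""
        p = make_protocol(matrix=32, n_segments=1, r_slice=1, r_pe=1,
                          n_slices=2)
        scheme = make_fov_shift_scheme([0.0])
        zero = np.zeros((1, 32, 32), dtype=complex)
        sens = np.stack([coils32.for_slice(0)])
        rec = simulate_shot(zero, sens, p, scheme, 0, noise_sigma=0.7,
                            rng=np.random.default_rng(11))
        samples = rec.imaging_band.real.ravel()   # 8*32*32 = 8192 > 1000
        assert samples.std() == pytest.approx(0.7, rel=0.05)
        assert rec.imaging_band.imag.ravel().std() == pytest.approx(0.7, rel=0.05)


class TestDataset:
    def test_reference_set_has_one_entry_per_anatomical_slice(self, sms64_clean):
        ref = sms64_clean.reference
        assert ref.central_segments.shape[0] == 2
        assert ref.phase_reference.shape[0] == 2

    def test_zero_motion_rate_leaves_all_shots_clean(self, sms64_clean):
        assert not any(s.corrupted for s in sms64_clean.shots.values())

    def test_fixed_seed_reproduces_shots_bit_identically(self, phantom32,
                                                         coils32):
        p = make_protocol(matrix=32, n_slices=2, n_directions=1)
        mm = MotionModel(rate=0.5)
        a = Simulator(phantom32, coils32, p, motion_model=mm, noise_sigma=0.3,
                      seed=13).acquire()
        b = Simulator(phantom32, coils32, p, motion_model=mm, noise_sigma=0.3,
                      seed=13).acquire()
        assert sorted(a.shots) == sorted(b.shots)
        for k in a.shots:
            assert np.array_equal(a.shots[k].imaging_band, b.shots[k].imaging_band)
            assert a.shots[k].corrupted == b.shots[k].corrupted

    def test_motion_events_hit_only_diffusion_weighted_shots(self, phantom32,
                                                             coils32):
        p = make_protocol(matrix=32, n_slices=2, n_directions=3)
        mm = MotionModel(rate=1.0)   # force events wherever allowed
        ds = Simulator(phantom32, coils32, p, motion_model=mm, seed=4).acquire()
        for s in ds.shots.values():
            if s.volume_index == 0:
                assert not s.corrupted
        dw = [s for s in ds.shots.values() if s.volume_index > 0]
        assert any(s.corrupted for s in dw)

    def test_corrupted_flag_tracks_forced_event(self, phantom32, coils32):
        p = make_protocol(matrix=32, n_slices=2, n_directions=1)
        ev = MotionEvent("x", 0, 1.0, (0.3, 0.1), 0.02)
        ds = Simulator(phantom32, coils32, p, seed=4,
                       forced_events={(1, 0, 1): ev}).acquire()
        assert ds.shots["v001_g00_s01"].corrupted
        assert not ds.shots["v001_g00_s00"].corrupted


class TestMultibandPulse:
    def test_single_slice_returns_base_pulse(self):
        t, base = make_sinc_pulse()
        wave, peak = multiband_pulse([0.0], (t, base))
        assert np.allclose(wave, base)
        assert peak == pytest.approx(np.abs(base).max())

    def test_peak_amplitude_scales_linearly_with_slice_count(self):
        t, base = make_sinc_pulse()
        _, p1 = multiband_pulse([0.0], (t, base))
        _, p3 = multiband_pulse([-30.0, 0.0, 30.0], (t, base))
        assert p3 == pytest.approx(3 * p1, rel=0.06)

    def test_spectrum_peaks_at_prescribed_slice_frequencies(self):
        t, base = make_sinc_pulse()
        wave, _ = multiband_pulse([-30.0, 0.0, 30.0], (t, base),
                                  grad_khz_per_mm=1.0)
        spec = np.abs(np.fft.fftshift(np.fft.fft(wave)))
        freqs = np.fft.fftshift(np.fft.fftfreq(t.size, d=t[1] - t[0]))
        floor = np.median(spec)
        for f0 in (-30.0, 0.0, 30.0):
            i = np.argmin(np.abs(freqs - f0))
            assert spec[i] > 100 * floor
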