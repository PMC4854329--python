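"""Distribution-width QC, reacquisition selection, navigator correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsepi_sms import (MotionEvent, ReacqPolicy, Simulator,
                       distribution_width, fit_slice_kernels,
                       navigator_phase_correct, per_slice_widths,
                       select_reacquisitions, simulate_contrast)
from rsepi_sms.caipi import make_fov_shift_scheme
from rsepi_sms.fourier import fft2c, ifft2c
from rsepi_sms.navigator import WidthReport
from rsepi_sms.scanner import motion_phase_map

from conftest import make_protocol, nrmse


class TestDistributionWidth:
    def test_all_signal_in_one_column_gives_zero_width(self):
        band = np.zeros((2, 4, 7), dtype=complex)
        band[:, :, 3] = 1.0
        rep = distribution_width(band)
        assert rep.w_x == 0.0
        assert rep.omega_x == 3

    def test_enumerated_three_column_example(self):
        """|S| = [1, 0, 1]: the peak ties resolve to the lowest index, so
        W = 1*0 + 0*1 + 1*2 = 2 (direct enumeration of the sum)."""
        band = np.array([[[1.0, 0.0, 1.0]]], dtype=complex)
        rep = distribution_width(band)
        assert rep.omega_x == 0
        assert rep.w_x == pytest.approx(2.0)

    def test_brute_force_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        band = rng.standard_normal((3, 5, 9)) + 1j * rng.standard_normal((3, 5, 9))
        rep = distribution_width(band)
        mag = np.abs(band)
        profile = np.sqrt((mag ** 2).sum(axis=(0, 1)))
        omega = int(np.argmax(profile))
        w = sum(mag[i, j, k] * abs(k - omega)
                for i in range(3) for j in range(5) for k in range(9))
        assert rep.omega_x == omega
        assert rep.w_x == pytest.approx(w, rel=1e-12)

    def test_quadratic_phase_strictly_increases_width(self, phantom32):
        """FFT oracle over a strength grid: adding stronger quadratic
        image-domain phase spreads navigator k-space monotonically."""
        con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
        img = con[0]
        widths = []
        for q in (0.0, 0.005, 0.01, 0.02, 0.04):
            ev = MotionEvent("x", 0, 0.0, (0.0, 0.0), q)
            phased = img * np.exp(1j * motion_phase_map(ev, 32, 32))
            nav = fft2c(phased[None])[:, :, 10:22]
            widths.append(distribution_width(nav).w_x)
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_all_zero_input_flagged_invalid(self):
        rep = distribution_width(np.zeros((2, 3, 4), dtype=complex))
        assert not rep.valid

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 4), st.floats(0, 2 * np.pi))
    def test_translation_and_global_phase_invariance(self, shift, angle):
        """Shifting the navigator along kx moves Omega_x with it and leaves
        W unchanged; a global unit phase never matters."""
        rng = np.random.default_rng(4)
        band = np.zeros((2, 4, 16), dtype=complex)
        band[:, :, 5:11] = rng.standard_normal((2, 4, 6)) \
            + 1j * rng.standard_normal((2, 4, 6))
        base = distribution_width(band)
        moved = distribution_width(np.roll(band, shift, axis=-1)
                                   * np.exp(1j * angle))
        assert moved.w_x == pytest.approx(base.w_x, rel=1e-12)
        assert moved.omega_x == base.omega_x + shift


class TestSelection:
    def _reports(self, widths, segments):
        return [WidthReport(shot_id=f"s{i:02d}", w_x=w, omega_x=0,
                            segment_index=seg)
                for i, (w, seg) in enumerate(zip(widths, segments))]

    def test_outlier_plus_runner_up_selected_at_default_fraction(self):
        widths = [1.0] * 9 + [50.0]
        segs = [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]
        reports = self._reports(widths, segs)
        picked = select_reacquisitions(reports, ReacqPolicy(), n_segments=5)
        assert len(picked) == 2          # ceil(0.2 * 10)
        assert "s09" in picked

    def test_equal_widths_fall_to_central_then_lowest_id(self):
        reports = self._reports([3.0] * 6, [0, 1, 2, 3, 4, 2])
        picked = select_reacquisitions(reports, ReacqPolicy(), n_segments=5)
        # central segment (index 2) shots outrank the rest; lowest id first
        assert picked == ["s02", "s05"]

    def test_central_weighting_outranks_edge_at_equal_raw_width(self):
        reports = self._reports([5.0, 5.0], [0, 2])
        picked = select_reacquisitions(reports, ReacqPolicy(fraction=0.5),
                                       n_segments=5)
        assert picked == ["s01"]

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ReacqPolicy(fraction=1.5)

    def test_selection_count_follows_ceiling(self):
        reports = self._reports(list(range(7)), [0] * 7)
        picked = select_reacquisitions(reports, ReacqPolicy(fraction=0.2),
                                       n_segments=5)
        assert len(picked) == 2          # ceil(1.4)


class TestNavigatorCorrection:
    def test_zero_phase_navigator_leaves_segment_unchanged(self):
        """A navigator whose image phase is identically zero (real,
        non-negative image) must not alter the segment."""
        rng = np.random.default_rng(2)
        seg = fft2c(rng.standard_normal((2, 16, 16))
                    + 1j * rng.standard_normal((2, 16, 16)))
        y = np.hanning(16)
        nav_img = (np.outer(y, y) + 0.05)[None].repeat(2, axis=0)
        nav = fft2c(nav_img.astype(complex))
        out = navigator_phase_correct(seg, nav, nav_kx_offset=0)
        assert nrmse(out, seg) < 1e-12

    def test_correction_removes_shotwise_phase_in_spliced_image(
            self, phantom64_pair):
        """Mild smooth shot-wise phase: corrected multi-shot magnitude is
        several times closer to truth than the uncorrected splice.
        (Thresholds derived from this simulator: full-phase removal keeps a
        band-truncation floor, so 'corrected' is ~0.07, uncorrected ~0.2.)"""
        ph, coils = phantom64_pair
        from rsepi_sms import ReconConfig, reconstruct
        p = make_protocol(matrix=64, n_segments=3, r_slice=1, r_pe=1,
                          n_slices=2, n_directions=1)
        rng = np.random.default_rng(9)
        forced = {}
        for g in range(2):
            for seg in range(3):
                ang = rng.uniform(0, 2 * np.pi)
                forced[(1, g, seg)] = MotionEvent(
                    f"g{g}s{seg}", g, rng.uniform(-np.pi, np.pi),
                    (0.15 * np.sin(ang), 0.15 * np.cos(ang)),
                    0.004 * rng.choice([-1.0, 1.0]))
        ds = Simulator(ph, coils, p, seed=21, forced_events=forced).acquire()
        tru = ds.truth["volumes"][1]
        from rsepi_sms import ReconConfig
        on = reconstruct(ds, ReconConfig(do_navigator_correction=True))
        off = reconstruct(ds, ReconConfig(do_navigator_correction=False))
        for s in range(2):
            e_on = nrmse(on.volumes[1, s], tru[s])
            e_off = nrmse(off.volumes[1, s], tru[s])
            assert e_on < 0.09
            assert e_off > 0.15
            assert e_off / e_on > 2.0

    def test_correction_is_idempotent(self):
        """Once the navigator phase is removed, re-deriving the navigator
        from corrected data and correcting again changes nothing."""
        rng = np.random.default_rng(6)
        img = (np.abs(rng.standard_normal((1, 16, 16))) + 0.2) \
            * np.exp(1j * rng.standard_normal((1, 16, 16)) * 0.5)
        seg = fft2c(img)
        once = navigator_phase_correct(seg, seg, nav_kx_offset=0)
        twice = navigator_phase_correct(once, once, nav_kx_offset=0)
        assert nrmse(twice, once) < 1e-12

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            navigator_phase_correct(np.zeros((2, 8, 8), complex),
                                    np.zeros((2, 6, 4), complex))


@pytest.fixture(scope="module")
def sliced_setup(phantom32, coils32):
    scheme = make_fov_shift_scheme(phantom32.slice_positions_mm)
    con = simulate_contrast(phantom32, 0.0, None, te_ms=70.0)
    k = np.stack([fft2c(con[s][None] * coils32.for_slice(s))
                  for s in range(2)])
    kern = fit_slice_kernels(k[:, :, :, 10:22], scheme, r_pe=2)
    return scheme, con, coils32, kern


class TestPerSliceWidths:

    def _collapsed_nav(self, scheme, con, coils, event=None):
        from rsepi_sms.caipi import slice_line_phase
        ky = np.arange(0, 32, 2)
        m = np.arange(ky.size)
        total = 0
        for j in range(2):
            img = con[j][None] * coils.for_slice(j)
            if event is not None and event.slice_index == j:
                img = img * np.exp(1j * motion_phase_map(event, 32, 32))
            k = fft2c(img)[:, ky, 10:22]
            total = total + k * np.exp(
                1j * slice_line_phase(scheme, j, m))[None, :, None]
        return total

    def test_corruption_localizes_to_the_corrupted_slice(self, sliced_setup):
        scheme, con, coils, kern = sliced_setup
        ev = MotionEvent("x", 0, 0.5, (0.4, 0.3), 0.03)
        nav = self._collapsed_nav(scheme, con, coils, ev)
        reports = per_slice_widths(nav, kern)
        assert reports[0].w_x > 1.2 * reports[1].w_x

    def test_clean_slices_have_comparable_widths(self, sliced_setup):
        scheme, con, coils, kern = sliced_setup
        nav = self._collapsed_nav(scheme, con, coils, None)
        reports = per_slice_widths(nav, kern)
        ratio = reports[0].w_x / reports[1].w_x
        assert 0.5 < ratio < 2.0

    def test_combined_width_bounded_by_per_slice_extremes(self, sliced_setup):
        """The aliased width lies between the per-slice widths once each is
        scaled by its share of the combined signal."""
        scheme, con, coils, kern = sliced_setup
        ev = MotionEvent("x", 0, 0.5, (0.4, 0.3), 0.03)
        nav = self._collapsed_nav(scheme, con, coils, ev)
        combined = distribution_width(nav).w_x
        reports = per_slice_widths(nav, kern)
        lo = min(r.w_x for r in reports)
        hi = sum(r.w_x for r in reports)
        assert lo <= combined <= 1.2 * hi
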