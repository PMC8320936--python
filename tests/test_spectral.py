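"""Reconstruction-chain unit tests, including a direct-DFT oracle."""

import numpy as np
import pytest

import doctvib as dv
from conftest import reconstruct


def _plain_frame(spectra, wavelength_nm, k_uniform=False):
    n = spectra.shape[1]
    return dv.SpectralFrame(
        spectra=spectra,
        wavelength_nm=wavelength_nm,
        timestamp_us=np.arange(n) * 100.0,
        line_period_us=100.0,
        k_uniform=k_uniform,
    )


def _k_uniform_wavelengths(n, lam_min=762.0, lam_max=938.0):
    k = np.linspace(2 * np.pi / lam_min, 2 * np.pi / lam_max, n)  # decreasing
    return 2 * np.pi / k  # increasing wavelengths, uniform in k


class TestSubtractBackground:
    def test_identical_alines_become_zero(self, source):
        spectra = np.tile(source.envelope[:, None], (1, 4))
        out = dv.subtract_background(_plain_frame(spectra, source.wavelength_nm))
        np.testing.assert_allclose(out.spectra, 0.0, atol=1e-15)

    def test_dc_peak_suppressed_by_20_db(self, source, single_reflector_phantom):
        acq = dv.AcquisitionConfig(alines_per_frame=8, noise_sd=1e-4)
        stim = [dv.VibrationStimulus(1000.0, 100.0)]
        frame = dv.simulate_bscan(single_reflector_phantom, stim, source, acq)
        raw = dv.to_ascans(dv.apodize(dv.k_linearize(frame), "hann"))
        sub = reconstruct(frame, source, background="mean")
        dc_raw = np.abs(raw.field[0, :]).mean()
        dc_sub = np.abs(sub.field[0, :]).mean()
        assert 20 * np.log10(dc_raw / dc_sub) >= 20.0

    def test_idempotent_on_zero_mean_frames(self, source):
        rng = np.random.default_rng(0)
        spectra = rng.normal(size=(source.pixel_count, 5))
        once = dv.subtract_background(_plain_frame(spectra, source.wavelength_nm))
        twice = dv.subtract_background(once)
        np.testing.assert_allclose(twice.spectra, once.spectra, atol=1e-12)

    def test_single_aline_needs_explicit_background(self, source):
        frame = _plain_frame(source.envelope[:, None], source.wavelength_nm)
        with pytest.raises(ValueError):
            dv.subtract_background(frame)
        out = dv.subtract_background(frame, background=source.envelope)
        np.testing.assert_allclose(out.spectra, 0.0, atol=1e-15)


class TestKLinearize:
    def test_identity_on_already_k_uniform_input(self):
        lam = _k_uniform_wavelengths(512)
        rng = np.random.default_rng(1)
        spectra = rng.normal(size=(512, 3))
        out = dv.k_linearize(_plain_frame(spectra, lam))
        assert out.k_uniform
        np.testing.assert_allclose(out.spectra, spectra, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(out.wavelength_nm, lam, rtol=1e-12)

    def test_removes_axial_blur_of_deep_reflector(self, source, single_reflector_phantom):
        """Nonlinear-in-k sampling chirps the fringe; k-linearization
        restores a transform-limited peak (smaller FWHM)."""
        acq = dv.AcquisitionConfig(alines_per_frame=2, noise_sd=0.0)
        frame = dv.simulate_bscan(single_reflector_phantom, [], source, acq)
        frame = dv.subtract_background(frame, background=source.envelope)

        def fwhm(frame, klin):
            if klin:
                f = dv.k_linearize(frame)
            else:
                # ablation: FFT the raw pixels as if uniformly spaced in k
                f = _plain_frame(
                    frame.spectra,
                    _k_uniform_wavelengths(frame.pixel_count),
                    k_uniform=True,
                )
            mag = np.abs(dv.to_ascans(dv.apodize(f, "hann")).field[:, 0])
            half = mag >= mag.max() / 2
            return int(half.sum())

        assert fwhm(frame, klin=True) < fwhm(frame, klin=False)

    def test_constant_spectrum_unchanged(self, source):
        spectra = np.full((source.pixel_count, 2), 3.25)
        out = dv.k_linearize(_plain_frame(spectra, source.wavelength_nm))
        np.testing.assert_allclose(out.spectra, 3.25, rtol=1e-9)

    def test_non_monotone_grid_rejected_at_construction(self):
        lam = np.linspace(800, 900, 64)
        lam[10] = lam[9]  # not strictly increasing
        with pytest.raises(ValueError, match="increasing"):
            _plain_frame(np.zeros((64, 2)), lam)


class TestApodize:
    def test_none_is_identity(self, source):
        frame = _plain_frame(np.ones((source.pixel_count, 2)), source.wavelength_nm)
        assert dv.apodize(frame, "none") is frame

    def test_unknown_window_rejected(self, source):
        frame = _plain_frame(np.ones((source.pixel_count, 2)), source.wavelength_nm)
        with pytest.raises(ValueError, match="window"):
            dv.apodize(frame, "blackmanharris")

    def test_hann_on_ones_replicates_the_window(self, source):
        n = source.pixel_count
        frame = _plain_frame(np.ones((n, 3)), source.wavelength_nm)
        out = dv.apodize(frame, "hann")
        np.testing.assert_allclose(out.spectra, np.hanning(n)[:, None] * np.ones(3))

    def test_hann_first_sidelobe_below_31_db(self, source, single_reflector_phantom):
        acq = dv.AcquisitionConfig(alines_per_frame=2, noise_sd=0.0)
        frame = dv.simulate_bscan(single_reflector_phantom, [], source, acq)
        bscan = reconstruct(frame, source, window="hann")
        mag = np.abs(bscan.field[:, 0])
        peak = int(mag.argmax())
        # first local minimum beyond the mainlobe, then the sidelobe max
        i = peak
        while i + 1 < mag.size and mag[i + 1] < mag[i]:
            i += 1
        sidelobe = mag[i : i + 40].max()
        assert 20 * np.log10(sidelobe / mag[peak]) <= -31.0


class TestToAscans:
    def test_zero_frame_gives_zero_bscan(self):
        lam = _k_uniform_wavelengths(128)
        bscan = dv.to_ascans(_plain_frame(np.zeros((128, 2)), lam, k_uniform=True))
        np.testing.assert_array_equal(bscan.field, 0.0)

    def test_requires_k_linearized_input(self, source):
        frame = _plain_frame(np.ones((source.pixel_count, 2)), source.wavelength_nm)
        with pytest.raises(ValueError, match="k-lineariz"):
            dv.to_ascans(frame)

    @pytest.mark.parametrize("cycles", [5, 23, 57])
    def test_pure_cosine_in_k_hits_the_predicted_bin(self, cycles):
        n, pad = 256, 2
        lam = _k_uniform_wavelengths(n)
        # column built in k-increasing order, then flipped to lambda order
        x = np.cos(2 * np.pi * cycles * np.arange(n) / n)[::-1]
        bscan = dv.to_ascans(
            _plain_frame(np.tile(x[:, None], (1, 2)), lam, k_uniform=True),
            pad_factor=pad,
        )
        assert int(np.abs(bscan.field[:, 0]).argmax()) == cycles * pad

    def test_parseval_on_kept_half(self):
        n = 256
        lam = _k_uniform_wavelengths(n)
        rng = np.random.default_rng(2)
        spectra = rng.normal(size=(n, 4))
        spectra -= spectra.mean(axis=0)  # suppress DC so the halves split evenly
        bscan = dv.to_ascans(_plain_frame(spectra, lam, k_uniform=True))
        kept = np.sum(np.abs(bscan.field) ** 2)
        total = np.sum(spectra**2)
        assert kept == pytest.approx(total / 2, rel=0.02)

    def test_matches_direct_dft_oracle_on_64_pixels(self):
        n, pad = 64, 2
        lam = _k_uniform_wavelengths(n)
        rng = np.random.default_rng(3)
        spectra = rng.normal(size=(n, 5))
        bscan = dv.to_ascans(_plain_frame(spectra, lam, k_uniform=True), pad_factor=pad)
        nfft = pad * n
        m = np.arange(nfft // 2)
        w = np.exp(-2j * np.pi * np.outer(np.arange(n), m) / nfft)
        oracle = (spectra[::-1, :].T @ w).T / np.sqrt(nfft)
        oracle *= np.exp(2j * np.pi * ((n - 1) / 2) * m / nfft)[:, None]
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(bscan.field, oracle, atol=1e-10 * scale)

    def test_shift_theorem_moves_the_peak_by_predicted_bins(self, source):
        acq = dv.AcquisitionConfig(alines_per_frame=2, noise_sd=0.0)
        peaks, axis = [], None
        for depth in (250.0, 310.0):
            ph = dv.SamplePhantom(reflectors=(dv.Reflector(depth, 0.2, "r"),))
            frame = dv.simulate_bscan(ph, [], source, acq)
            bscan = reconstruct(frame, source)
            peaks.append(int(np.abs(bscan.field[:, 0]).argmax()))
            axis = bscan.depth_axis_um
        predicted = 60.0 / np.diff(axis)[0]
        assert abs((peaks[1] - peaks[0]) - predicted) <= 1.0

    def test_linearity_of_the_chain_up_to_log_scaling(self, source, single_reflector_phantom):
        acq = dv.AcquisitionConfig(alines_per_frame=2, noise_sd=0.0)
        frame = dv.simulate_bscan(single_reflector_phantom, [], source, acq)
        frame = dv.subtract_background(frame, background=source.envelope)
        scaled = dv.SpectralFrame(
            spectra=frame.spectra * 3.0,
            wavelength_nm=frame.wavelength_nm,
            timestamp_us=frame.timestamp_us,
            line_period_us=frame.line_period_us,
        )
        b1 = dv.to_ascans(dv.apodize(dv.k_linearize(frame), "hann"))
        b3 = dv.to_ascans(dv.apodize(dv.k_linearize(scaled), "hann"))
        np.testing.assert_allclose(np.abs(b3.field), 3 * np.abs(b1.field), atol=1e-9)


class TestLogMagnitude:
    def _bscan(self, field):
        return dv.ComplexBScan(
            field=field, depth_axis_um=np.arange(field.shape[0], dtype=float),
            line_period_us=100.0,
        )

    def test_unit_magnitude_is_zero_db(self):
        img = dv.log_magnitude(self._bscan(np.ones((8, 4), dtype=complex)))
        np.testing.assert_allclose(img.log_magnitude_db, 0.0, atol=1e-9)

    def test_doubling_raises_by_6_02_db(self):
        field = np.ones((8, 4), dtype=complex)
        field[3, 2] = 2.0
        img = dv.log_magnitude(self._bscan(field), floor_db=-100, ceiling_db=100)
        assert img.log_magnitude_db[3, 2] - img.log_magnitude_db[0, 0] == pytest.approx(
            20 * np.log10(2), abs=1e-6
        )

    def test_zero_pixels_clip_to_the_floor(self):
        field = np.ones((8, 4), dtype=complex)
        field[0, 0] = 0.0
        img = dv.log_magnitude(self._bscan(field), floor_db=-60, ceiling_db=0)
        assert img.log_magnitude_db[0, 0] == -60.0
        assert np.all(np.isfinite(img.log_magnitude_db))

    def test_inverted_display_range_rejected(self):
        with pytest.raises(ValueError):
            dv.log_magnitude(
                self._bscan(np.ones((4, 2), dtype=complex)), floor_db=0, ceiling_db=0
            )
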