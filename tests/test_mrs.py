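"""MEGA-PRESS quantification chain: IO, preprocessing, correction, QC,
integration, and planted-value recovery."""

import os
from dataclasses import replace

import numpy as np
import pytest

from gabasupp import mrs
from gabasupp.cohort import synthesize_scan


def _lorentzian_block(fwhm_hz=4.0, ppm=3.0, amplitude=1.0, seed=None):
    """Raw time-domain block holding a single Lorentzian line."""
    t = np.arange(mrs.N_RAW) * mrs.DWELL_S
    t2 = 1.0 / (np.pi * fwhm_hz)
    f = (ppm - mrs.CENTER_PPM) * mrs.F_TX_MHZ
    fid = amplitude * np.exp(2j * np.pi * f * t - t / t2)
    if seed is not None:
        rng = np.random.default_rng(seed)
        fid = fid + 0.0 * rng.standard_normal(t.size)
    return mrs.BlockSpectrum(values=fid, edit_state="Off")


def _measure_fwhm_hz(block):
    ppm = block.ppm_axis
    y = block.values.real
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = i
    while y[left] > half:
        left -= 1
    right = i
    while y[right] > half:
        right += 1
    # linear interpolation at the half-height crossings
    p_left = np.interp(half, [y[left], y[left + 1]], [ppm[left], ppm[left + 1]])
    p_right = np.interp(half, [y[right], y[right - 1]], [ppm[right], ppm[right - 1]])
    return abs(p_left - p_right) * mrs.F_TX_MHZ


class TestRdaBundleIO:
    def test_roundtrip_values_and_bytes(self, tmp_path):
        scan = synthesize_scan(0.09, snr=20, seed=5)
        d1 = tmp_path / "b1"
        mrs.write_rda_bundle(scan, str(d1))
        back = mrs.read_rda_bundle(str(d1))
        assert len(back.on_blocks) == 16 and len(back.off_blocks) == 16
        for a, b in zip(scan.blocks, back.blocks):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.edit_state == b.edit_state
            assert a.block_index == b.block_index
        d2 = tmp_path / "b2"
        mrs.write_rda_bundle(back, str(d2))
        for name in sorted(os.listdir(d1)):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_wrong_point_count_rejected(self, tmp_path):
        block = _lorentzian_block()
        block = replace(block, values=block.values[:1000])
        path = tmp_path / "short.rda"
        mrs.write_rda_block(replace(block, values=np.pad(block.values, (0, 24))),
                            str(path))
        text = path.read_text().splitlines()
        # claim 1024 points but provide 1000
        body = text[:8] + text[8:8 + 1000]
        path.write_text("\n".join(body) + "\n")
        with pytest.raises(mrs.RdaParseError, match="VectorSize"):
            mrs.read_rda_block(str(path))

    def test_missing_edit_state_rejected(self, tmp_path):
        block = _lorentzian_block()
        path = tmp_path / "x.rda"
        mrs.write_rda_block(block, str(path))
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("EditState")]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(mrs.RdaParseError, match="EditState"):
            mrs.read_rda_block(str(path))

    def test_malformed_header_line_rejected(self, tmp_path):
        block = _lorentzian_block()
        path = tmp_path / "x.rda"
        mrs.write_rda_block(block, str(path))
        path.write_text("garbage header line\n" + path.read_text())
        with pytest.raises(mrs.RdaParseError, match="malformed"):
            mrs.read_rda_block(str(path))


class TestPreprocess:
    def test_output_length_and_idempotence_guard(self):
        out = mrs.preprocess(_lorentzian_block())
        assert out.n_points == mrs.N_PROC
        assert out.domain == "freq"
        with pytest.raises(mrs.InvalidBlockError):
            mrs.preprocess(out)

    def test_zero_signal_maps_to_zero(self):
        block = mrs.BlockSpectrum(values=np.zeros(mrs.N_RAW, complex),
                                  edit_state="Off")
        out = mrs.preprocess(block)
        assert np.allclose(out.values, 0.0)

    def test_linewidth_broadened_peak_position_kept(self):
        """4-Hz Lorentzian apodized with the 4-Hz Gaussian: Voigt FWHM must
        land between 4 and 10 Hz and the peak must not move."""
        raw = _lorentzian_block(fwhm_hz=4.0, ppm=3.0)
        out = mrs.preprocess(raw)
        fwhm = _measure_fwhm_hz(out)
        assert 4.0 < fwhm < 10.0
        peak_ppm = out.ppm_axis[int(np.argmax(out.values.real))]
        bin_ppm = abs(out.ppm_axis[1] - out.ppm_axis[0])
        assert abs(peak_ppm - 3.0) <= bin_ppm

    def test_apodization_equals_spectral_convolution(self):
        """Independent oracle: multiplying the FID by the Gaussian window is
        the same as convolving the unapodized spectrum with a 4-Hz Gaussian."""
        raw = _lorentzian_block(fwhm_hz=4.0, ppm=3.0)
        out = mrs.preprocess(raw)
        plain = mrs._fid_to_spectrum(raw.values, mrs.N_PROC)
        freqs = np.arange(-200, 201) * (1.0 / (mrs.N_PROC * mrs.DWELL_S))
        sigma = mrs.APOD_LB_HZ / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        kernel = np.exp(-0.5 * (freqs / sigma) ** 2)
        kernel /= kernel.sum()
        oracle = np.convolve(plain.real, kernel, mode="same")
        i = int(np.argmax(out.values.real))
        sl = slice(i - 100, i + 100)
        np.testing.assert_allclose(out.values.real[sl], oracle[sl], rtol=0.02)


class TestPhaseFrequencyCorrection:
    @pytest.mark.parametrize("phase,shift", [(0.5, 0.02), (-0.4, -0.015),
                                             (1.2, 0.0), (0.0, 0.03)])
    def test_known_corruption_recovered(self, phase, shift):
        clean = mrs.preprocess(_lorentzian_block(fwhm_hz=1.0))
        corrupted = mrs.apply_phase_shift(clean, phase, shift)
        est_phase, est_shift = mrs.phase_and_frequency_correct(corrupted)
        assert abs(est_phase - phase) < 0.05
        assert abs(est_shift - shift) < 0.005

    def test_already_corrected_is_fixed_point(self):
        clean = mrs.preprocess(_lorentzian_block(fwhm_hz=1.0))
        phase, shift = mrs.phase_and_frequency_correct(clean)
        assert abs(phase) < 0.05 and abs(shift) < 0.005

    def test_pure_noise_flagged_uncorrectable(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(mrs.N_RAW) + 1j * rng.standard_normal(mrs.N_RAW)
        block = mrs.preprocess(mrs.BlockSpectrum(values=noise, edit_state="Off"))
        with pytest.raises(mrs.UncorrectableBlockError):
            mrs.phase_and_frequency_correct(block)

    def test_pair_correction_identity_and_restore(self):
        clean = mrs.preprocess(_lorentzian_block(fwhm_hz=1.0))
        same = mrs.apply_pair_correction(clean, 0.0, 0.0)
        np.testing.assert_allclose(same.values, clean.values, atol=1e-9)
        corrupted = mrs.apply_phase_shift(clean, 0.5, 0.02)
        restored = mrs.apply_pair_correction(corrupted, 0.5, 0.02)
        np.testing.assert_allclose(restored.values, clean.values,
                                   atol=1e-6 * np.abs(clean.values).max())

    def test_mismatched_pairing_rejected(self):
        on = mrs.preprocess(_lorentzian_block())
        off = replace(mrs.preprocess(_lorentzian_block()), block_index=3)
        with pytest.raises(mrs.PairingError):
            mrs.apply_pair_correction(replace(on, block_index=1), 0.1, 0.0,
                                      off=off)


def _freq_blocks_from(base_real, n_blocks, edit_state, perturb=None):
    blocks = []
    for b in range(n_blocks):
        vals = base_real.astype(complex).copy()
        if perturb is not None:
            vals = perturb(b, vals)
        blocks.append(mrs.BlockSpectrum(values=vals, edit_state=edit_state,
                                        block_index=b, domain="freq"))
    return blocks


class TestQc:
    def _base(self):
        ppm = mrs._ppm_axis(mrs.N_PROC, mrs.DWELL_S, mrs.F_TX_MHZ, mrs.CENTER_PPM)
        return np.exp(-0.5 * ((ppm - 3.0) / 0.02) ** 2) * 100.0

    def test_identical_blocks_no_deviants(self):
        base = self._base()
        scan = mrs.EditedScan(on_blocks=_freq_blocks_from(base, 4, "On"),
                              off_blocks=_freq_blocks_from(base, 4, "Off"))
        report = mrs.qc_blocks(scan, max_deviant=0)
        assert all(c == 0 for c in report.deviant_counts.values())
        assert report.excluded == []
        assert report.exclusion_fraction == 0.0

    def test_planted_spike_block_excluded_exactly(self):
        base = self._base()
        k = 40

        def spike(b, vals):
            if b == 2:
                vals[100:100 + k] += 500.0
            return vals

        scan = mrs.EditedScan(
            on_blocks=_freq_blocks_from(base, 8, "On", perturb=spike),
            off_blocks=_freq_blocks_from(base, 8, "Off"))
        report = mrs.qc_blocks(scan, max_deviant=k - 1)
        assert report.excluded == [("On", 2)]

    def test_exclusion_fraction_tracks_planted_corruption(self):
        base = self._base()
        bad = {1, 5}

        def corrupt(b, vals):
            if b in bad:
                vals[200:600] += 800.0
            return vals

        scan = mrs.EditedScan(
            on_blocks=_freq_blocks_from(base, 16, "On", perturb=corrupt),
            off_blocks=_freq_blocks_from(base, 16, "Off", perturb=corrupt))
        report = mrs.qc_blocks(scan, max_deviant=300)
        assert report.exclusion_fraction == pytest.approx(4 / 32)

    def test_all_excluded_aborts(self):
        base = self._base()
        rng = np.random.default_rng(0)

        def wild(b, vals):
            return vals + 1000.0 * rng.standard_normal(vals.size)

        scan = mrs.EditedScan(
            on_blocks=_freq_blocks_from(base, 8, "On", perturb=wild),
            off_blocks=_freq_blocks_from(base, 8, "Off", perturb=wild))
        with pytest.raises(mrs.QcError):
            mrs.qc_blocks(scan, max_deviant=0)


class TestDifferenceAndSum:
    def test_on_equals_off_cancels(self):
        base = TestQc()._base()
        scan = mrs.EditedScan(on_blocks=_freq_blocks_from(base, 4, "On"),
                              off_blocks=_freq_blocks_from(base, 4, "Off"))
        diff, summed = mrs.difference_and_sum(scan)
        assert np.allclose(diff.values, 0.0)
        np.testing.assert_allclose(summed.values.real, 2 * base)

    def test_edited_feature_survives_only_in_diff(self):
        scan = synthesize_scan(0.09, snr=np.inf, seed=0,
                               phase_jitter=0.0, shift_jitter=0.0)
        on = [mrs.preprocess(b) for b in scan.on_blocks]
        off = [mrs.preprocess(b) for b in scan.off_blocks]
        diff, _ = mrs.difference_and_sum(
            mrs.EditedScan(on_blocks=on, off_blocks=off))
        gaba = mrs.integrate_peak(diff, *mrs.GABA_WINDOW)
        assert gaba > 0
        off_area = mrs.integrate_peak(off[0], *mrs.GABA_WINDOW)
        on_area = mrs.integrate_peak(on[0], *mrs.GABA_WINDOW)
        assert on_area - off_area == pytest.approx(gaba, rel=1e-6)

    def test_linearity_under_scaling(self):
        base = TestQc()._base()
        scan = mrs.EditedScan(on_blocks=_freq_blocks_from(2 * base, 4, "On"),
                              off_blocks=_freq_blocks_from(base, 4, "Off"))
        diff, summed = mrs.difference_and_sum(scan)
        scan2 = mrs.EditedScan(on_blocks=_freq_blocks_from(4 * base, 4, "On"),
                               off_blocks=_freq_blocks_from(2 * base, 4, "Off"))
        diff2, summed2 = mrs.difference_and_sum(scan2)
        np.testing.assert_allclose(diff2.values, 2 * diff.values)
        np.testing.assert_allclose(summed2.values, 2 * summed.values)


class TestIntegratePeak:
    def _gaussian_spectrum(self, amplitude=50.0, sigma_ppm=0.01, ppm0=3.0):
        ppm = mrs._ppm_axis(mrs.N_PROC, mrs.DWELL_S, mrs.F_TX_MHZ, mrs.CENTER_PPM)
        vals = amplitude * np.exp(-0.5 * ((ppm - ppm0) / sigma_ppm) ** 2)
        return mrs.BlockSpectrum(values=vals.astype(complex), edit_state="Sum",
                                 domain="freq")

    def test_zero_spectrum_integrates_to_zero(self):
        spec = mrs.BlockSpectrum(values=np.zeros(mrs.N_PROC, complex),
                                 edit_state="Sum", domain="freq")
        assert mrs.integrate_peak(spec, 2.85, 3.15) == 0.0

    def test_gaussian_closed_form(self):
        a, sigma = 50.0, 0.01
        spec = self._gaussian_spectrum(a, sigma)
        area = mrs.integrate_peak(spec, 3.0 - 5 * sigma, 3.0 + 5 * sigma)
        assert area == pytest.approx(a * sigma * np.sqrt(2 * np.pi), rel=0.005)

    def test_reversed_window_rejected(self):
        spec = self._gaussian_spectrum()
        with pytest.raises(ValueError, match="reversed"):
            mrs.integrate_peak(spec, 3.15, 2.85)

    def test_window_outside_axis_rejected(self):
        spec = self._gaussian_spectrum()
        with pytest.raises(ValueError, match="outside"):
            mrs.integrate_peak(spec, 20.0, 25.0)


class TestGabaCrRatio:
    def test_scale_invariance(self):
        scan = synthesize_scan(0.09, snr=np.inf, seed=2)
        est1 = mrs.gaba_cr_ratio(scan)
        doubled = mrs.EditedScan(
            on_blocks=[replace(b, values=2 * b.values) for b in scan.on_blocks],
            off_blocks=[replace(b, values=2 * b.values) for b in scan.off_blocks],
            scan_id=scan.scan_id)
        est2 = mrs.gaba_cr_ratio(doubled)
        assert est2.gaba_cr == pytest.approx(est1.gaba_cr, rel=1e-9)

    def test_monotone_in_planted_gaba(self):
        values = [mrs.gaba_cr_ratio(synthesize_scan(g, snr=np.inf, seed=3)).gaba_cr
                  for g in (0.03, 0.06, 0.09, 0.12)]
        assert np.all(np.diff(values) > 0)

    def test_null_metabolite_gives_near_zero(self):
        est = mrs.gaba_cr_ratio(synthesize_scan(0.0, snr=np.inf, seed=4))
        assert abs(est.gaba_cr) < 1e-3

    def test_deterministic_given_seed(self):
        a = synthesize_scan(0.09, snr=30, seed=11)
        b = synthesize_scan(0.09, snr=30, seed=11)
        for x, y in zip(a.blocks, b.blocks):
            np.testing.assert_array_equal(x.values, y.values)
        assert mrs.gaba_cr_ratio(a).gaba_cr == mrs.gaba_cr_ratio(b).gaba_cr

    def test_monte_carlo_mean_at_snr20(self):
        """8 scans per subject at block SNR 20: the mean estimate over 50
        subjects stays within 5% of the planted 0.09."""
        rng = np.random.default_rng(77)
        subject_means = []
        for _ in range(50):
            vals = [mrs.gaba_cr_ratio(
                synthesize_scan(0.09, snr=20, seed=int(rng.integers(2 ** 31)))
            ).gaba_cr for _ in range(8)]
            subject_means.append(np.mean(vals))
        assert np.mean(subject_means) == pytest.approx(0.09, rel=0.05)
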