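"""Spectral estimators: grids, periodograms, normalization, attenuation,
line fits, scatterer spacing and form-factor fits, parametric maps."""

import numpy as np
import pytest

from qusrad import (
    EstimationError,
    ParametricMap,
    PowerSpectrum,
    ScattererField,
    SpectralConfig,
    attenuation_correct,
    build_parametric_maps,
    diffuse_field,
    estimate_ace,
    estimate_power_spectrum,
    estimate_sas,
    fit_form_factor,
    fit_spectral_line,
    make_subroi_grid,
    normalize_spectrum,
    regular_field,
    simulate_rf_frame,
)
from qusrad.spectral import _form_factor_model_db

from conftest import EXTENT, reference_spectrum, window_spectrum

BAND = (4e6, 9e6)


class TestSubROIGrid:
    def test_two_nonoverlapping_windows(self, acq):
        wh = int(round(2e-3 / acq.axial_step))
        ww = int(round(2e-3 / acq.line_pitch))
        mask = np.zeros((2 * wh + 5, ww + 2), dtype=bool)
        mask[:2 * wh, :ww] = True
        grid = make_subroi_grid(mask, acq, window_mm=2.0, overlap=0.0)
        assert grid.n_valid == 2

    def test_stride_at_94_percent_overlap(self, acq):
        wh = int(round(2e-3 / acq.axial_step))
        mask = np.ones((6 * wh, 40), dtype=bool)
        grid = make_subroi_grid(mask, acq, window_mm=2.0, overlap=0.94)
        assert grid.stride_samples == max(1, round(wh * 0.06))
        # 2 mm x 6% = 0.12 mm stride
        assert grid.stride_samples * acq.axial_step == pytest.approx(
            0.12e-3, rel=0.2
        )

    def test_grid_matches_brute_force_enumeration(self, acq):
        rng = np.random.default_rng(0)
        mask = np.zeros((400, 40), dtype=bool)
        mask[30:360, 4:36] = True
        mask[100:150, 10:20] = False  # hole
        grid = make_subroi_grid(mask, acq, window_mm=2.0, overlap=0.94)
        wh, ww = grid.window_samples, grid.window_lines
        brute = 0
        for r0 in grid.row_origins:
            for c0 in grid.col_origins:
                brute += mask[r0 : r0 + wh, c0 : c0 + ww].all()
        assert grid.n_valid == brute

    def test_empty_or_small_roi_rejected(self, acq):
        with pytest.raises(EstimationError):
            make_subroi_grid(np.zeros((300, 30), bool), acq)
        small = np.zeros((300, 30), bool)
        small[:20, :3] = True
        with pytest.raises(EstimationError, match="window"):
            make_subroi_grid(small, acq)


class TestPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self, acq):
        t = np.arange(256) / acq.sampling_rate
        win = np.tile(np.sin(2 * np.pi * 6e6 * t)[:, None], (1, 4))
        spec = estimate_power_spectrum(win, acq)
        assert abs(spec.frequencies[np.argmax(spec.values_db)] - 6e6) < 2 * (
            spec.frequencies[1] - spec.frequencies[0]
        )

    def test_line_averaging_shrinks_variance(self, acq):
        """64-line averaging reduces per-bin periodogram sd ~8x."""
        rng = np.random.default_rng(1)
        single_sd, avg_sd = [], []
        for _ in range(40):
            win = rng.standard_normal((256, 64))
            lin64 = estimate_power_spectrum(win, acq).linear()
            lin1 = estimate_power_spectrum(win[:, :2], acq).linear()
            band = slice(30, 90)
            avg_sd.append(np.std(lin64[band]))
            single_sd.append(np.std(lin1[band]))
        ratio = np.mean(single_sd) / np.mean(avg_sd)
        assert 4.0 < ratio < 9.5  # sqrt(64/2) = 5.7 expected for the 2-line ref

    def test_half_window_halves_resolution(self, acq):
        rng = np.random.default_rng(2)
        win = rng.standard_normal((256, 4))
        full = estimate_power_spectrum(win, acq)
        half = estimate_power_spectrum(win[:128], acq)
        df_full = full.frequencies[1] - full.frequencies[0]
        df_half = half.frequencies[1] - half.frequencies[0]
        assert df_half == pytest.approx(2 * df_full)

    def test_zero_window_rejected(self, acq):
        with pytest.raises(EstimationError):
            estimate_power_spectrum(np.zeros((128, 4)), acq)
        with pytest.raises(EstimationError):
            estimate_power_spectrum(np.zeros((128, 1)), acq)


class TestNormalization:
    def _spec(self, db):
        f = np.linspace(3e6, 10e6, 50)
        return PowerSpectrum(f, np.full(50, float(db)))

    def test_self_normalization_zero(self):
        out = normalize_spectrum(self._spec(-12.0), self._spec(-12.0))
        np.testing.assert_allclose(out.values_db, 0.0)

    def test_constant_offset(self):
        out = normalize_spectrum(self._spec(-6.0), self._spec(-12.0))
        np.testing.assert_allclose(out.values_db, 6.0)

    def test_band_restriction(self):
        out = normalize_spectrum(self._spec(0), self._spec(0), BAND)
        assert out.frequencies[0] >= BAND[0] and out.frequencies[-1] <= BAND[1]

    def test_mismatched_grids_rejected(self):
        a = self._spec(0)
        b = PowerSpectrum(np.linspace(2e6, 9e6, 50), np.zeros(50))
        with pytest.raises(ValueError):
            normalize_spectrum(a, b)


def _attenuated_stack(alpha, depths_m, f):
    """Synthetic normalized spectra following the 4*alpha*f*z convention."""
    out = []
    for z in depths_m:
        db = -4.0 * alpha * (z * 100) * (f / 1e6)
        out.append((z, PowerSpectrum(f, db)))
    return out


class TestACE:
    F = np.linspace(4e6, 9e6, 40)

    def test_depth_independent_spectra_give_zero(self):
        stack = _attenuated_stack(0.0, [0.01, 0.02, 0.03], self.F)
        assert estimate_ace(stack) == 0.0

    def test_exact_convention_recovery(self):
        stack = _attenuated_stack(0.8, [0.01, 0.015, 0.02, 0.025], self.F)
        assert estimate_ace(stack) == pytest.approx(0.8, abs=1e-9)

    def test_negative_slope_clamped_to_zero(self):
        stack = _attenuated_stack(-0.5, [0.01, 0.02, 0.03], self.F)
        assert estimate_ace(stack) == 0.0

    def test_single_depth_rejected(self):
        with pytest.raises(EstimationError):
            estimate_ace(_attenuated_stack(1.0, [0.02], self.F))

    def test_simulation_recovery(self, acq, pulse, ref_frames):
        """Frames simulated at alpha = 1.0 dB/cm/MHz against a lossless
        phantom recover ACE within 0.15 (5-seed spot check; the wider
        20-seed study runs in the acceptance suite)."""
        aces = []
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            fr = simulate_rf_frame(
                diffuse_field(EXTENT, 2e8, rng), pulse, acq, attenuation=1.0
            )
            stack = []
            for r0 in range(150, 1000, 100):
                s = window_spectrum(fr, r0, 104, 512)
                ref = reference_spectrum(ref_frames, r0, 104, 512)
                stack.append(
                    ((r0 + 52) * acq.axial_step, normalize_spectrum(s, ref, BAND))
                )
            aces.append(estimate_ace(stack))
        assert np.mean(aces) == pytest.approx(1.0, abs=0.15)

    def test_correction_inverts_estimation(self):
        stack = _attenuated_stack(0.6, [0.01, 0.02, 0.03], self.F)
        ace = estimate_ace(stack)
        corrected = [(z, attenuation_correct(s, ace, z)) for z, s in stack]
        assert estimate_ace(corrected) == pytest.approx(0.0, abs=1e-9)

    def test_zero_ace_correction_is_identity(self):
        s = PowerSpectrum(self.F, np.linspace(-3, 3, 40))
        out = attenuation_correct(s, 0.0, 0.02)
        np.testing.assert_array_equal(out.values_db, s.values_db)


class TestSpectralLineFit:
    F = np.linspace(4e6, 9e6, 50)

    def test_flat_zero_spectrum(self):
        fit = fit_spectral_line(PowerSpectrum(self.F, np.zeros(50)))
        assert fit.ss == pytest.approx(0, abs=1e-12)
        assert fit.si == pytest.approx(0, abs=1e-12)
        assert fit.mbf == pytest.approx(0, abs=1e-12)

    def test_exact_line_recovered(self):
        y = 2.0 * self.F / 1e6 - 5.0
        fit = fit_spectral_line(PowerSpectrum(self.F, y), eval_freq_hz=6.5e6)
        assert fit.ss == pytest.approx(2.0, abs=1e-9)
        assert fit.si == pytest.approx(-5.0, abs=1e-9)
        assert fit.mbf == pytest.approx(2.0 * 6.5 - 5.0, abs=1e-9)

    def test_offset_moves_mbf_si_not_ss(self):
        y = 1.5 * self.F / 1e6 + 2.0
        a = fit_spectral_line(PowerSpectrum(self.F, y))
        b = fit_spectral_line(PowerSpectrum(self.F, y + 3.0))
        assert b.ss == pytest.approx(a.ss, abs=1e-9)
        assert b.si == pytest.approx(a.si + 3.0, abs=1e-9)
        assert b.mbf == pytest.approx(a.mbf + 3.0, abs=1e-9)

    def test_consistency_identity(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(50)
        fit = fit_spectral_line(PowerSpectrum(self.F, y))
        assert fit.mbf == pytest.approx(fit.ss * fit.f_eval_mhz + fit.si, abs=1e-9)

    def test_matches_closed_form_ols(self):
        """polyfit agrees with the closed-form two-parameter OLS solution."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.standard_normal(50) * 5
            fit = fit_spectral_line(PowerSpectrum(self.F, y))
            x = self.F / 1e6
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            inter = y.mean() - slope * x.mean()
            assert fit.ss == pytest.approx(slope, rel=1e-9, abs=1e-12)
            assert fit.si == pytest.approx(inter, rel=1e-9, abs=1e-12)

    def test_ss_unbiased_under_noise(self):
        """1 dB white noise on an exact line leaves SS unbiased
        (< 0.05 dB/MHz over replicates at 50 bins)."""
        rng = np.random.default_rng(5)
        errs = [
            fit_spectral_line(
                PowerSpectrum(self.F, 2.0 * self.F / 1e6 - 5.0 + rng.standard_normal(50))
            ).ss
            - 2.0
            for _ in range(200)
        ]
        assert abs(np.mean(errs)) < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(EstimationError):
            fit_spectral_line(PowerSpectrum(self.F[:2], np.zeros(2)))


class TestSAS:
    def test_pure_cosine_spectrum_exact_lag(self, acq):
        f = np.arange(4e6, 9e6, 20e3)
        delta = 1.54e6  # 0.5 mm spacing
        lin = 1.0 + 0.9 * np.cos(2 * np.pi * f / delta)
        spec = PowerSpectrum(f, 10 * np.log10(np.maximum(lin, 1e-6)))
        sas, ok = estimate_sas(spec, acq)
        assert ok
        assert sas == pytest.approx(acq.sound_speed / (2 * delta), rel=0.03)

    def test_simulated_spacing_recovered(self, acq, pulse, ref_frames):
        d = 0.5e-3
        rng = np.random.default_rng(11)
        fld = regular_field(EXTENT, d, rng, jitter=0.01e-3)
        fr = simulate_rf_frame(fld, pulse, acq)
        s = window_spectrum(fr, 200, 512, 1024)
        ref = reference_spectrum(ref_frames, 200, 512, 1024)
        sas, ok = estimate_sas(normalize_spectrum(s, ref, BAND), acq)
        assert ok
        assert sas == pytest.approx(d, abs=0.02e-3)

    def test_monotone_in_true_spacing(self, acq, pulse, ref_frames):
        """Recovered spacing increases with the true lattice spacing."""
        got = []
        for d in (0.30e-3, 0.42e-3, 0.55e-3, 0.70e-3, 0.85e-3):
            rng = np.random.default_rng(21)
            fld = regular_field(EXTENT, d, rng, jitter=0.005e-3)
            fr = simulate_rf_frame(fld, pulse, acq)
            s = window_spectrum(fr, 200, 512, 1024)
            ref = reference_spectrum(ref_frames, 200, 512, 1024)
            sas, ok = estimate_sas(normalize_spectrum(s, ref, BAND), acq)
            assert ok
            got.append(sas)
        assert np.all(np.diff(got) > 0)

    def test_diffuse_mostly_invalid(self, acq, pulse, ref_frames):
        """Fully diffuse media carry no dominant periodicity: the majority
        of windows must be flagged invalid."""
        flags = []
        for seed in range(6):
            rng = np.random.default_rng(600 + seed)
            fr = simulate_rf_frame(diffuse_field(EXTENT, 2e8, rng), pulse, acq)
            for r0 in range(150, 900, 150):
                s = window_spectrum(fr, r0, 104, 512, cols=[0, 10, 20])
                ref = reference_spectrum(ref_frames, r0, 104, 512)
                _, ok = estimate_sas(normalize_spectrum(s, ref, BAND), acq)
                flags.append(ok)
        assert np.mean(flags) < 0.5

    def test_band_too_narrow_rejected(self, acq):
        f = np.linspace(4e6, 4.2e6, 10)
        with pytest.raises(EstimationError):
            estimate_sas(PowerSpectrum(f, np.zeros(10)), acq, (1.9, 2.0))


class TestFormFactor:
    def test_exact_model_self_consistency(self, acq):
        f = np.linspace(4e6, 9e6, 60)
        a_true = 90e-6
        y = _form_factor_model_db(f, a_true, acq.sound_speed) + 7.0
        spec = PowerSpectrum(f, y - 40 * np.log10(f / 1e6))  # as-normalized form
        asd, aac, ok = fit_form_factor(spec, acq)
        assert ok
        assert asd == pytest.approx(a_true, rel=0.02)
        assert aac == pytest.approx(7.0, abs=0.2)

    def test_amplitude_offset_separability(self, acq):
        f = np.linspace(4e6, 9e6, 60)
        y = _form_factor_model_db(f, 120e-6, acq.sound_speed) - 40 * np.log10(f / 1e6)
        a1, c1, _ = fit_form_factor(PowerSpectrum(f, y), acq)
        a2, c2, _ = fit_form_factor(PowerSpectrum(f, y + 10.0), acq)
        assert c2 - c1 == pytest.approx(10.0, abs=1e-6)
        assert a2 == pytest.approx(a1, rel=1e-6)

    def test_rayleigh_limit_pins_and_flags(self, acq):
        """A pure f^4 spectrum (vanishing diameter) pins the search at the
        lower bound and is flagged invalid."""
        f = np.linspace(4e6, 9e6, 60)
        spec = PowerSpectrum(f, np.zeros(60))  # normalized Rayleigh: flat
        asd, _, ok = fit_form_factor(spec, acq)
        assert not ok
        assert asd == pytest.approx(1e-6, rel=0.01)

    def test_non_finite_rejected(self, acq):
        f = np.linspace(4e6, 9e6, 10)
        vals = np.zeros(10)
        vals[3] = np.nan
        with pytest.raises(EstimationError):
            fit_form_factor(PowerSpectrum(f, vals), acq)


def _roi_for(frame, z0, z1, x0, x1, acq):
    mask = np.zeros(frame.samples.shape, dtype=bool)
    r0 = int(z0 / acq.axial_step)
    r1 = int(z1 / acq.axial_step)
    c0 = int(x0 / acq.line_pitch)
    c1 = int(x1 / acq.line_pitch)
    mask[r0:r1, c0:c1] = True
    return mask


@pytest.fixture(scope="module")
def homo_run(acq, pulse, ref_frames):
    rng = np.random.default_rng(33)
    fr = simulate_rf_frame(
        diffuse_field(EXTENT, 2e8, rng), pulse, acq, attenuation=0.5,
        seed=1, noise_rel=0.002,
    )
    roi = _roi_for(fr, 0.005, 0.019, 0.0006, 0.0058, acq)
    cfg = SpectralConfig(overlap=0.75)
    maps, ace = build_parametric_maps(fr, roi, ref_frames, cfg)
    return fr, roi, cfg, maps, ace


class TestParametricMaps:
    def test_map_shapes_match_grid(self, homo_run, acq):
        fr, roi, cfg, maps, _ = homo_run
        grid = make_subroi_grid(roi, acq, cfg.window_mm, cfg.overlap)
        for m in maps.values():
            assert m.values.shape == grid.shape

    def test_homogeneous_mbf_cv_below_20pct(self, homo_run):
        *_, maps, _ = homo_run
        m = maps["MBF"]
        vals = m.values[m.valid_mask]
        # MBF is in dB: CV on the linear-power scale
        lin = 10 ** (vals / 10)
        assert np.std(lin) / np.mean(lin) < 0.2 or np.std(vals) < 2.0

    def test_frame_ace_recovered(self, homo_run):
        *_, ace = homo_run
        assert ace == pytest.approx(0.5, abs=0.15)

    def test_deterministic(self, homo_run, ref_frames):
        fr, roi, cfg, maps, ace = homo_run
        maps2, ace2 = build_parametric_maps(fr, roi, ref_frames, cfg)
        assert ace2 == ace
        for k in maps:
            np.testing.assert_array_equal(maps[k].values, maps2[k].values)
            np.testing.assert_array_equal(maps[k].valid_mask, maps2[k].valid_mask)

    def test_two_region_density_contrast_in_aac(self, acq, pulse, ref_frames):
        """4x density in the lower half raises the AAC map there by ~6 dB
        (10 log10 4); spot check over 3 seeds, full study in acceptance."""
        diffs = []
        for seed in range(3):
            rng = np.random.default_rng(70 + seed)
            mid = 0.013
            dmap = lambda z, x: np.where(np.asarray(z) >= mid, 4.0, 1.0)
            fld = diffuse_field(EXTENT, 1e8, rng, density_map=dmap)
            fr = simulate_rf_frame(fld, pulse, acq)
            roi = _roi_for(fr, 0.005, 0.021, 0.0006, 0.0058, acq)
            maps, _ = build_parametric_maps(
                fr, roi, ref_frames, SpectralConfig(overlap=0.5)
            )
            m = maps["AAC"]
            grid = make_subroi_grid(roi, acq, 2.0, 0.5)
            depths = grid.window_center_depths(acq)
            lower = depths >= mid + 1e-3
            upper = depths <= mid - 1e-3
            diffs.append(
                m.values[lower][m.valid_mask[lower]].mean()
                - m.values[upper][m.valid_mask[upper]].mean()
            )
        assert np.mean(diffs) == pytest.approx(6.0, abs=2.0)

    def test_invalid_map_error(self, acq, pulse, ref_frames):
        """An ROI smaller than a window fails with a named error rather
        than returning empty maps."""
        rng = np.random.default_rng(8)
        fr = simulate_rf_frame(diffuse_field(EXTENT, 2e8, rng), pulse, acq)
        roi = _roi_for(fr, 0.005, 0.006, 0.001, 0.0015, acq)
        with pytest.raises(EstimationError):
            build_parametric_maps(fr, roi, ref_frames)
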