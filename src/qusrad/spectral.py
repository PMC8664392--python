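"""First-order QUS parameter estimation from normalized power spectra.

Implements the classical quantitative-ultrasound spectroscopy chain: a
sliding sub-ROI window over the tumor ROI, per-window Hann-tapered,
line-averaged periodograms, reference-phantom normalization, a
spectral-difference attenuation estimate (ACE) used for depth correction,
and per-window estimators for the seven spectral parameters:

=====  =============================================================
MBF    mid-band fit: linear fit to the normalized dB spectrum
       evaluated at the band center (dB)
SS     spectral slope of that fit (dB/MHz)
SI     spectral intercept at 0 MHz (dB)
SAS    spacing among scatterers, from the dominant periodicity of the
       normalized power spectrum (m)
ASD    acoustic scatterer diameter, from a spherical-Gaussian
       form-factor fit (m)
AAC    average acoustic concentration: fitted amplitude offset of the
       form-factor model (dB)
ACE    attenuation coefficient estimate (dB/cm/MHz), one per frame
=====  =============================================================

Attenuation convention (used consistently by the simulator, the estimator
and the corrector): the normalized power spectrum of echoes from depth z
loses ``4 * alpha * f_MHz * z_cm`` dB relative to the unattenuated
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionSpec

__all__ = [
    "SpectralConfig",
    "SubROIGrid",
    "PowerSpectrum",
    "SpectralFit",
    "ParametricMap",
    "EstimationError",
    "make_subroi_grid",
    "estimate_power_spectrum",
    "normalize_spectrum",
    "estimate_ace",
    "attenuation_correct",
    "fit_spectral_line",
    "estimate_sas",
    "fit_form_factor",
    "build_parametric_maps",
]

_DB_PER_NEPER10 = 10.0 / np.log(10.0)  # 10*log10(e^x) = x * 4.3429...


class EstimationError(ValueError):
    """Raised when an estimator's preconditions cannot be met."""


@dataclass(frozen=True)
class SpectralConfig:
    """Tunable parameters of the spectral-estimation chain.

    window_mm / overlap follow the sliding sub-ROI convention (2 mm square
    windows, 94% overlap); nfft_oversample zero-pads the FFT for a smoother
    frequency grid; SAS and ASD searches are bounded to physically sensible
    ranges for soft tissue.
    """

    window_mm: float = 2.0
    overlap: float = 0.94
    band_mhz: tuple[float, float] = (4.0, 9.0)
    nfft_oversample: int = 4
    sas_range_mm: tuple[float, float] = (0.1, 2.0)
    sas_min_peak: float = 0.45
    asd_range_um: tuple[float, float] = (1.0, 300.0)
    asd_grid_points: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.band_mhz[0] >= self.band_mhz[1]:
            raise ValueError("band must be increasing")

    @property
    def band_hz(self) -> tuple[float, float]:
        return (self.band_mhz[0] * 1e6, self.band_mhz[1] * 1e6)

    @property
    def eval_freq_hz(self) -> float:
        """Frequency at which MBF is evaluated: the analysis-band midpoint."""
        return 0.5 * (self.band_hz[0] + self.band_hz[1])


@dataclass
class SubROIGrid:
    """Lattice of analysis-window origins inside an ROI mask.

    ``valid[i, j]`` marks lattice cells whose full window footprint lies
    inside the ROI; invalid lattice cells are carried (so maps keep the
    lattice shape) but never analyzed.
    """

    window_samples: int
    window_lines: int
    stride_samples: int
    stride_lines: int
    row_origins: np.ndarray
    col_origins: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_origins), len(self.col_origins))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def window_center_depths(self, acq: AcquisitionSpec) -> np.ndarray:
        """Depth (m) of each lattice row's window center."""
        return (self.row_origins + self.window_samples / 2.0) * acq.axial_step


@dataclass
class PowerSpectrum:
    """Line-averaged power spectrum in dB on a uniform frequency grid."""

    frequencies: np.ndarray
    values_db: np.ndarray
    n_lines_averaged: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values_db = np.asarray(self.values_db, dtype=float)
        if self.frequencies.shape != self.values_db.shape:
            raise ValueError("frequency/value shape mismatch")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def band(self, band_hz: tuple[float, float]) -> "PowerSpectrum":
        lo, hi = band_hz
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        return PowerSpectrum(
            self.frequencies[sel], self.values_db[sel], self.n_lines_averaged
        )

    def linear(self) -> np.ndarray:
        return 10.0 ** (self.values_db / 10.0)


@dataclass(frozen=True)
class SpectralFit:
    """MBF/SS/SI triple; satisfies mbf = ss * f_eval_mhz + si."""

    mbf: float
    ss: float
    si: float
    f_eval_mhz: float


@dataclass
class ParametricMap:
    """One QUS parameter on the sub-ROI lattice, with validity mask."""

    parameter_name: str
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values/valid_mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values flagged valid")

    def mean(self) -> float:
        if not self.valid_mask.any():
            raise EstimationError(f"map {self.parameter_name} has no valid cells")
        return float(self.values[self.valid_mask].mean())


# ---------------------------------------------------------------------------
# sub-ROI grid


def make_subroi_grid(
    roi_mask: np.ndarray,
    acq: AcquisitionSpec,
    window_mm: float = 2.0,
    overlap: float = 0.94,
) -> SubROIGrid:
    """Lay a sliding-window lattice over an ROI mask.

    The window is ``window_mm`` square in physical units (axial extent
    converted through c / (2 fs) per sample, lateral through the line
    pitch); the stride is the window extent times (1 - overlap), floored at
    one sample/line.  Windows whose footprint touches the ROI complement
    are marked invalid.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("roi_mask must be 2D")
    wh = max(2, int(round(window_mm * 1e-3 / acq.axial_step)))
    ww = max(2, int(round(window_mm * 1e-3 / acq.line_pitch)))
    if not mask.any():
        raise EstimationError(
            f"ROI is empty; need at least one {wh} sample x {ww} line window"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    if (r1 - r0) < wh or (c1 - c0) < ww:
        raise EstimationError(
            f"ROI ({r1 - r0} samples x {c1 - c0} lines) smaller than one "
            f"analysis window ({wh} samples x {ww} lines)"
        )
    stride_r = max(1, int(round(wh * (1.0 - overlap))))
    stride_c = max(1, int(round(ww * (1.0 - overlap))))
    row_origins = np.arange(r0, r1 - wh + 1, stride_r)
    col_origins = np.arange(c0, c1 - ww + 1, stride_c)

    # integral image -> full-footprint test per lattice cell
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    R, C = np.meshgrid(row_origins, col_origins, indexing="ij")
    sums = ii[R + wh, C + ww] - ii[R, C + ww] - ii[R + wh, C] + ii[R, C]
    valid = sums == wh * ww
    if not valid.any():
        raise EstimationError(
            f"no analysis window ({wh} samples x {ww} lines) fits fully "
            "inside the ROI"
        )
    return SubROIGrid(wh, ww, stride_r, stride_c, row_origins, col_origins, valid)


# ---------------------------------------------------------------------------
# spectra


def _taper(n: int) -> np.ndarray:
    return np.hanning(n)


def _batch_linear_spectra(windows: np.ndarray, nfft: int) -> np.ndarray:
    """(n, h, w) RF windows -> (n, nfft//2+1) line-averaged linear power."""
    w = _taper(windows.shape[1])
    tapered = windows * w[None, :, None]
    spec = np.fft.rfft(tapered, n=nfft, axis=1)
    power = (np.abs(spec) ** 2).mean(axis=2) / np.sum(w**2)
    return power


def estimate_power_spectrum(
    rf_window: np.ndarray,
    acq: AcquisitionSpec,
    nfft: int | None = None,
) -> PowerSpectrum:
    """Hann-tapered periodogram per scan line, averaged across lines (dB).

    Raises :class:`EstimationError` for windows with fewer than 2 lines or
    zero total power (log of zero).
    """
    arr = np.asarray(rf_window, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise EstimationError("window must be 2D with >= 2 scan lines")
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(arr.shape[0])))
    power = _batch_linear_spectra(arr[None, :, :], nfft)[0]
    if not np.any(power > 0):
        raise EstimationError("window has zero power; cannot take log spectrum")
    freqs = np.fft.rfftfreq(nfft, d=1.0 / acq.sampling_rate)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    return PowerSpectrum(freqs, db, n_lines_averaged=arr.shape[1])


def normalize_spectrum(
    sample: PowerSpectrum,
    reference: PowerSpectrum,
    band_hz: tuple[float, float] | None = None,
) -> PowerSpectrum:
    """dB subtraction of the reference-phantom spectrum (calibration).

    Removes the system/pulse transfer function.  When ``band_hz`` is given
    the result is restricted to the analysis band.
    """
    if sample.frequencies.shape != reference.frequencies.shape or not np.allclose(
        sample.frequencies, reference.frequencies
    ):
        raise ValueError("sample and reference frequency grids differ")
    out = PowerSpectrum(
        sample.frequencies,
        sample.values_db - reference.values_db,
        sample.n_lines_averaged,
    )
    return out.band(band_hz) if band_hz is not None else out


# ---------------------------------------------------------------------------
# attenuation


def estimate_ace(spectra_by_depth) -> float:
    """Spectral-difference attenuation estimate in dB/cm/MHz.

    ``spectra_by_depth`` is an iterable of ``(depth_m, PowerSpectrum)`` of
    normalized spectra on a common grid.  For each frequency the dB value
    is regressed against depth (cm); the per-frequency slopes are mapped to
    attenuation through the 4*f path factor and averaged over the band.
    Negative estimates are clamped to zero.
    """
    items = list(spectra_by_depth)
    depths = np.array([d for d, _ in items], dtype=float)
    if np.unique(np.round(depths, 9)).size < 2:
        raise EstimationError("need >= 2 distinct depths for attenuation estimation")
    grid = items[0][1].frequencies
    vals = np.vstack([s.values_db for _, s in items])
    z_cm = depths * 100.0
    z_cm = z_cm - z_cm.mean()
    slopes = z_cm @ (vals - vals.mean(axis=0)) / np.sum(z_cm**2)  # dB per cm per bin
    f_mhz = grid / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_f = -slopes / (4.0 * f_mhz)
    alpha = float(np.nanmean(alpha_f[f_mhz > 0]))
    return max(alpha, 0.0)


def attenuation_correct(
    spectrum: PowerSpectrum, ace: float, depth_m: float
) -> PowerSpectrum:
    """Undo depth-cumulative attenuation: add 4 * ace * z_cm * f_MHz dB."""
    if depth_m < 0:
        raise ValueError("depth must be non-negative")
    gain = 4.0 * ace * (depth_m * 100.0) * (spectrum.frequencies / 1e6)
    return PowerSpectrum(
        spectrum.frequencies, spectrum.values_db + gain, spectrum.n_lines_averaged
    )


# ---------------------------------------------------------------------------
# spectral-line fit


def fit_spectral_line(
    spectrum: PowerSpectrum,
    band_hz: tuple[float, float] | None = None,
    eval_freq_hz: float | None = None,
) -> SpectralFit:
    """Ordinary least squares of dB against frequency (MHz) over the band.

    SS is the slope (dB/MHz), SI the intercept at 0 MHz, MBF the fitted
    value at ``eval_freq_hz`` (default: band midpoint).
    """
    spec = spectrum.band(band_hz) if band_hz is not None else spectrum
    if spec.frequencies.size < 3:
        raise EstimationError("need >= 3 frequency bins in band for the line fit")
    f_mhz = spec.frequencies / 1e6
    if eval_freq_hz is None:
        eval_freq_hz = 0.5 * (spec.frequencies[0] + spec.frequencies[-1])
    ss, si = np.polyfit(f_mhz, spec.values_db, 1)
    f_eval = eval_freq_hz / 1e6
    return SpectralFit(
        mbf=float(ss * f_eval + si), ss=float(ss), si=float(si), f_eval_mhz=f_eval
    )


# ---------------------------------------------------------------------------
# scatterer spacing (SAS)


def _spectrum_autocorr(p: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of a (detrended) spectrum over freq lags."""
    x = p - p.mean()
    r = np.correlate(x, x, mode="full")[x.size - 1 :]
    if r[0] <= 0:
        return np.zeros_like(r)
    return r / r[0]


def estimate_sas(
    spectrum: PowerSpectrum,
    acq: AcquisitionSpec,
    sas_range_mm: tuple[float, float] = (0.1, 2.0),
    min_peak: float = 0.45,
) -> tuple[float, bool]:
    """Scatterer-spacing estimate from power-spectrum periodicity.

    Quasi-regular scatterer spacing d imprints a frequency comb with tooth
    spacing c / (2 d) on the normalized power spectrum.  The linear-scale
    spectrum is flattened (divided by a smooth moving-average envelope),
    autocorrelated over frequency lags, and the dominant peak in the lag
    range corresponding to ``sas_range_mm`` is located with parabolic
    interpolation; SAS = c / (2 * lag).

    Returns ``(sas_m, valid)``; ``valid`` is False when no autocorrelation
    peak rises above ``min_peak`` (diffuse media), in which case the value
    must be excluded via the map's validity mask.
    """
    f = spectrum.frequencies
    if f.size < 8:
        raise EstimationError("spectrum too short for spacing analysis")
    df = f[1] - f[0]
    bandwidth = f[-1] - f[0]
    p = spectrum.linear()
    # flatten residual spectral tilt with a moving-average envelope
    k = max(5, int(round(1e6 / df)) | 1)
    pad = np.pad(p, k // 2, mode="edge")
    env = np.convolve(pad, np.ones(k) / k, mode="valid")
    flat = p / np.maximum(env, 1e-30) - 1.0
    r = _spectrum_autocorr(flat)
    c = acq.sound_speed
    lag_lo = max(c / (2.0 * sas_range_mm[1] * 1e-3), 2.5 * df)
    lag_hi = min(c / (2.0 * sas_range_mm[0] * 1e-3), 0.75 * bandwidth)
    lo = int(np.ceil(lag_lo / df))
    hi = int(np.floor(lag_hi / df))
    if hi - lo < 2:
        raise EstimationError("band does not span the requested spacing range")
    seg = r[lo : hi + 1]
    i = int(np.argmax(seg)) + lo
    peak = r[i]
    is_local_max = 0 < i < r.size - 1 and r[i] >= r[i - 1] and r[i] >= r[i + 1]
    if peak < min_peak or not is_local_max:
        return float("nan"), False
    # parabolic sub-bin refinement
    y0, y1, y2 = r[i - 1], r[i], r[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    lag = (i + np.clip(delta, -0.5, 0.5)) * df
    return float(c / (2.0 * lag)), True


# ---------------------------------------------------------------------------
# form-factor fit (ASD / AAC)


def _form_factor_model_db(f_hz: np.ndarray, a_m, sound_speed: float) -> np.ndarray:
    """10*log10(f^4 * exp(-0.827 (k a / 2)^2)) with k = 2 pi f / c.

    Shape-only (unit amplitude); broadcasting over an array of diameters is
    supported (a_m of shape (..., 1) against f of shape (n,)).
    """
    f = np.asarray(f_hz, dtype=float)
    with np.errstate(divide="ignore"):
        rayleigh = 40.0 * np.log10(f / 1e6)
    u = (np.pi * f * np.asarray(a_m) / sound_speed) ** 2  # (k a / 2)^2
    return rayleigh - 0.827 * u * _DB_PER_NEPER10


def fit_form_factor(
    spectrum: PowerSpectrum,
    acq: AcquisitionSpec,
    asd_range_um: tuple[float, float] = (1.0, 300.0),
    grid_points: int = 60,
    reference_is_rayleigh: bool = True,
) -> tuple[float, float, bool]:
    """Spherical-Gaussian form-factor fit: effective diameter and amplitude.

    The model for the apparent backscatter in dB is
    ``10 log10(C f^4 exp(-0.827 (k a / 2)^2)) + A``; the diameter ``a`` is
    found by log-spaced grid search (refined once), the amplitude ``A`` in
    closed form per candidate.  With ``reference_is_rayleigh`` (default) the
    phantom's known Rayleigh f^4 backscatter is first restored onto the
    normalized spectrum, which is what makes the f^4 factor in the model
    meaningful after calibration.

    Returns ``(asd_m, aac_db, valid)``; ``valid`` is False when the best
    diameter pins at a search bound (e.g. spectra with no measurable
    roll-off in band).
    """
    y = np.asarray(spectrum.values_db, dtype=float)
    if not np.all(np.isfinite(y)):
        raise EstimationError("non-finite spectrum in form-factor fit")
    f = spectrum.frequencies
    if reference_is_rayleigh:
        y = y + 40.0 * np.log10(f / 1e6)

    def best_on(grid_um):
        a = grid_um[:, None] * 1e-6
        m = _form_factor_model_db(f, a, acq.sound_speed)  # (g, n)
        resid = y[None, :] - m
        amp = resid.mean(axis=1)
        mse = ((resid - amp[:, None]) ** 2).mean(axis=1)
        j = int(np.argmin(mse))
        return j, grid_um, amp

    lo, hi = asd_range_um
    grid = np.geomspace(lo, hi, grid_points)
    j, grid, amp = best_on(grid)
    pinned = j in (0, grid.size - 1)
    if not pinned:
        fine = np.linspace(grid[j - 1], grid[j + 1], 41)
        j2, fine, amp2 = best_on(fine)
        a_best, a_amp = fine[j2], amp2[j2]
    else:
        a_best, a_amp = grid[j], amp[j]
    return float(a_best * 1e-6), float(a_amp), not pinned


# ---------------------------------------------------------------------------
# parametric maps


def _reference_row_spectra(
    reference_frames,
    grid: SubROIGrid,
    nfft: int,
) -> dict[int, np.ndarray]:
    """Depth-matched reference spectra: linear power averaged over all
    reference frames and lateral window positions at each lattice row."""
    out: dict[int, np.ndarray] = {}
    wh, ww = grid.window_samples, grid.window_lines
    for r0 in grid.row_origins:
        acc, n = 0.0, 0
        for fr in reference_frames:
            if fr.n_samples < r0 + wh:
                raise EstimationError(
                    "reference frames shallower than the sample ROI depth range"
                )
            cols = np.arange(0, fr.n_lines - ww + 1, ww)
            wins = np.stack([fr.samples[r0 : r0 + wh, c : c + ww] for c in cols])
            acc = acc + _batch_linear_spectra(wins, nfft).sum(axis=0)
            n += len(cols)
        out[int(r0)] = acc / n
    return out


def build_parametric_maps(
    frame,
    roi_mask: np.ndarray,
    reference_frames,
    config: SpectralConfig | None = None,
) -> tuple[dict[str, ParametricMap], float]:
    """Full first-order QUS analysis of one frame.

    Returns ``(maps, ace)`` where ``maps`` holds one :class:`ParametricMap`
    per parameter in {MBF, SS, SI, SAS, ASD, AAC} on the sub-ROI lattice
    (no map for ACE) and ``ace`` is the frame-level attenuation estimate
    used for the spectral correction.  Per-window estimator failures become
    invalid cells; an entirely invalid map raises.
    """
    config = config or SpectralConfig()
    acq = frame.acquisition
    grid = make_subroi_grid(roi_mask, acq, config.window_mm, config.overlap)
    wh, ww = grid.window_samples, grid.window_lines
    nfft = int(2 ** np.ceil(np.log2(wh * config.nfft_oversample)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / acq.sampling_rate)
    band_sel = (freqs >= config.band_hz[0]) & (freqs <= config.band_hz[1])
    f_band = freqs[band_sel]

    ii, jj = np.nonzero(grid.valid)
    wins = np.stack(
        [
            frame.samples[
                grid.row_origins[i] : grid.row_origins[i] + wh,
                grid.col_origins[j] : grid.col_origins[j] + ww,
            ]
            for i, j in zip(ii, jj)
        ]
    )
    sample_pow = np.vstack(
        [
            _batch_linear_spectra(wins[k : k + 512], nfft)
            for k in range(0, wins.shape[0], 512)
        ]
    )
    ref_pow = _reference_row_spectra(reference_frames, grid, nfft)
    ref_rows = np.stack([ref_pow[int(grid.row_origins[i])] for i in ii])
    with np.errstate(divide="ignore"):
        norm_db = 10.0 * np.log10(np.maximum(sample_pow, 1e-300)) - 10.0 * np.log10(
            ref_rows
        )
    norm_db = norm_db[:, band_sel]

    # frame-level ACE from row-averaged normalized spectra
    depths = grid.window_center_depths(acq)
    row_spectra = []
    for i in np.unique(ii):
        mean_db = norm_db[ii == i].mean(axis=0)
        row_spectra.append((depths[i], PowerSpectrum(f_band, mean_db)))
    if len(row_spectra) >= 2:
        ace = estimate_ace(row_spectra)
    else:
        warnings.warn("single-depth ROI: ACE fixed at 0", stacklevel=2)
        ace = 0.0

    gain = 4.0 * ace * (depths[ii, None] * 100.0) * (f_band[None, :] / 1e6)
    corr_db = norm_db + gain

    shape = grid.shape
    names = ["MBF", "SS", "SI", "SAS", "ASD", "AAC"]
    vals = {n: np.full(shape, np.nan) for n in names}
    ok = {n: np.zeros(shape, dtype=bool) for n in names}
    for k, (i, j) in enumerate(zip(ii, jj)):
        spec = PowerSpectrum(f_band, corr_db[k])
        try:
            fit = fit_spectral_line(spec, eval_freq_hz=config.eval_freq_hz)
        except EstimationError:
            fit = None
        if fit is not None and np.isfinite([fit.mbf, fit.ss, fit.si]).all():
            vals["MBF"][i, j], vals["SS"][i, j], vals["SI"][i, j] = (
                fit.mbf,
                fit.ss,
                fit.si,
            )
            ok["MBF"][i, j] = ok["SS"][i, j] = ok["SI"][i, j] = True
        try:
            sas, sas_ok = estimate_sas(
                spec, acq, config.sas_range_mm, config.sas_min_peak
            )
        except EstimationError:
            sas, sas_ok = np.nan, False
        if sas_ok:
            vals["SAS"][i, j], ok["SAS"][i, j] = sas, True
        try:
            asd, aac, ff_ok = fit_form_factor(
                spec, acq, config.asd_range_um, config.asd_grid_points
            )
        except EstimationError:
            ff_ok = False
        if ff_ok:
            vals["ASD"][i, j], vals["AAC"][i, j] = asd, aac
            ok["ASD"][i, j] = ok["AAC"][i, j] = True

    maps = {}
    for n in names:
        if not ok[n].any():
            raise EstimationError(f"all sub-ROIs invalid for parameter {n}")
        maps[n] = ParametricMap(n, np.nan_to_num(vals[n]), ok[n])
    return maps, ace
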