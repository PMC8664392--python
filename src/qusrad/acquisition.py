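"""Acquisition metadata and transmit-pulse models.

The acquisition model mirrors a clinical linear-array scanner operating
around 7 MHz: raw beamformed radiofrequency (RF) lines are digitized at a
sampling rate well above the analysis band and quantized to a fixed bit
depth.  All downstream spectral estimation (windowing, FFT bin spacing,
depth/sample conversion) is driven by this metadata rather than by
hard-coded constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSpec", "PulseModel", "default_acquisition", "default_pulse"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitization and geometry metadata for one RF acquisition.

    Parameters
    ----------
    sampling_rate : float
        RF sampling frequency in Hz.
    center_frequency : float
        Transducer center frequency in Hz.
    analysis_band : tuple of float
        (low, high) analysis band edges in Hz; must bracket the center
        frequency and satisfy Nyquist against ``sampling_rate``.
    sound_speed : float
        Assumed speed of sound in m/s (soft-tissue convention 1540).
    bit_depth : int
        ADC resolution; 8 or 16.
    line_pitch : float
        Lateral spacing between adjacent scan lines in m.
    """

    sampling_rate: float = 40e6
    center_frequency: float = 7e6
    analysis_band: tuple[float, float] = (4e6, 9e6)
    sound_speed: float = 1540.0
    bit_depth: int = 16
    line_pitch: float = 0.2e-3

    def __post_init__(self) -> None:
        lo, hi = self.analysis_band
        if not lo < self.center_frequency < hi:
            raise ValueError(
                f"analysis band {self.analysis_band} must bracket the "
                f"center frequency {self.center_frequency}"
            )
        if self.sampling_rate <= 2 * hi:
            raise ValueError("sampling_rate must exceed twice the band's upper edge")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.line_pitch <= 0 or self.sound_speed <= 0:
            raise ValueError("line_pitch and sound_speed must be positive")

    @property
    def axial_step(self) -> float:
        """Axial distance per RF sample in m (pulse-echo: c / (2 fs))."""
        return self.sound_speed / (2.0 * self.sampling_rate)

    @property
    def band_center(self) -> float:
        """Midpoint of the analysis band in Hz."""
        return 0.5 * (self.analysis_band[0] + self.analysis_band[1])

    def depth_of_sample(self, sample_index) -> np.ndarray:
        """Depth in m corresponding to an RF sample index (0 -> transducer face)."""
        return np.asarray(sample_index, dtype=float) * self.axial_step


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-enveloped sinusoidal transmit/receive pulse.

    ``fractional_bandwidth`` is the -6 dB (amplitude) full spectral width
    divided by the center frequency.  The default 5/7 places the -6 dB edges
    at 4.5 and 9.5 MHz for a 7 MHz pulse, so the 4-9 MHz analysis band stays
    within the usable bandwidth.
    """

    center_frequency: float = 7e6
    fractional_bandwidth: float = 5.0 / 7.0
    envelope: str = field(default="gaussian")

    def __post_init__(self) -> None:
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.envelope != "gaussian":
            raise ValueError("only the gaussian envelope is implemented")

    @property
    def sigma_t(self) -> float:
        """Gaussian envelope standard deviation in seconds.

        Chosen so the amplitude spectrum drops 6 dB at
        ``center_frequency * (1 +/- fractional_bandwidth / 2)``.
        """
        bw_hz = self.fractional_bandwidth * self.center_frequency
        return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bw_hz)

    def spectrum(self, freqs: np.ndarray) -> np.ndarray:
        """Real zero-phase amplitude spectrum sampled at ``freqs`` (Hz).

        Analytic transform of exp(-t^2/(2 sigma^2)) cos(2 pi f0 t); the
        negative-frequency lobe is included so very wideband pulses remain
        exact.
        """
        f = np.asarray(freqs, dtype=float)
        s2 = 2.0 * (np.pi * self.sigma_t) ** 2
        lobe = np.exp(-s2 * (f - self.center_frequency) ** 2)
        lobe = lobe + np.exp(-s2 * (f + self.center_frequency) ** 2)
        return 0.5 * self.sigma_t * np.sqrt(2.0 * np.pi) * lobe

    def time_series(self, sampling_rate: float, n_sigma: float = 4.0):
        """Sampled symmetric pulse, support +/- ``n_sigma`` envelope widths."""
        half = int(np.ceil(n_sigma * self.sigma_t * sampling_rate))
        t = np.arange(-half, half + 1) / sampling_rate
        p = np.exp(-(t**2) / (2.0 * self.sigma_t**2)) * np.cos(
            2.0 * np.pi * self.center_frequency * t
        )
        return t, p


def default_acquisition() -> AcquisitionSpec:
    """The package-default acquisition: 40 MHz / 16-bit, 7 MHz probe, 4-9 MHz band."""
    return AcquisitionSpec()


def default_pulse() -> PulseModel:
    return PulseModel()
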