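"""Shared fixtures: acquisition defaults, reference phantom, helpers.

Everything is generated programmatically; the reference phantom is built
once per session because averaging its frames is the slowest shared step.
"""

from __future__ import annotations

import numpy as np
import pytest

from qusrad import (
    PowerSpectrum,
    default_acquisition,
    default_pulse,
    make_reference_frames,
)
from qusrad.spectral import _batch_linear_spectra

EXTENT = (0.002, 0.024, 0.0, 0.0064)  # shared simulation field (z0, z1, x0, x1) m


@pytest.fixture(scope="session")
def acq():
    return default_acquisition()


@pytest.fixture(scope="session")
def pulse():
    return default_pulse()


@pytest.fixture(scope="session")
def ref_frames(acq, pulse):
    return make_reference_frames(acq, pulse, seed=1, extent=EXTENT)


def window_spectrum(frame, r0, wh, nfft, cols=None, ww=10):
    """Line-averaged linear->dB spectrum of one or more frame windows."""
    acq = frame.acquisition
    if cols is None:
        cols = range(0, frame.n_lines - ww + 1, ww)
    wins = np.stack([frame.samples[r0 : r0 + wh, c : c + ww] for c in cols])
    p = _batch_linear_spectra(wins, nfft).mean(axis=0)
    freqs = np.fft.rfftfreq(nfft, 1.0 / acq.sampling_rate)
    return PowerSpectrum(freqs, 10.0 * np.log10(p))


def reference_spectrum(frames, r0, wh, nfft):
    """Depth-matched average reference spectrum over phantom frames."""
    lin = np.mean(
        [window_spectrum(f, r0, wh, nfft).linear() for f in frames], axis=0
    )
    freqs = np.fft.rfftfreq(nfft, 1.0 / frames[0].acquisition.sampling_rate)
    return PowerSpectrum(freqs, 10.0 * np.log10(lin))


@pytest.fixture(scope="session")
def spectrum_helpers():
    return window_spectrum, reference_spectrum
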