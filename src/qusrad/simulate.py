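"""Synthetic raw-RF data: scatterer fields, frames, phantoms and cohorts.

The generator provides ground-truthed stand-ins for every input the
pipeline consumes: beamformed RF frames of point-scatterer media, matching
reference-phantom frames, tumor ROI masks, and outcome-labeled cohorts.

Physical model (deliberately reduced):

* each scatterer is a point reflector at a continuous (axial, lateral)
  position; its echo is the transmit pulse delayed by the two-way travel
  time 2 z / c — synthesis is done per scan line in the frequency domain,
  so sub-sample (fractional-delay) positions are exact;
* per-scatterer amplitude filtering combines the Rayleigh f^2 amplitude
  dependence, a spherical-Gaussian form factor parameterized by an
  effective scatterer diameter, and frequency-dependent attenuation;
* attenuation follows the package-wide convention that the power spectrum
  of echoes from depth z loses 4 * alpha * f_MHz * z_cm dB (alpha in
  dB/cm/MHz), i.e. an amplitude factor 10^(-4 alpha f z / 20);
* no lateral point-spread coupling, diffraction or beamforming: one
  scatterer contributes only to its nearest scan line.

This captures exactly the statistics the spectral and texture estimators
consume (comb spectra from quasi-regular spacing, density-proportional
incoherent power, form-factor roll-off, depth-cumulative attenuation)
without full wave propagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec, PulseModel, default_acquisition, default_pulse

__all__ = [
    "ScattererField",
    "RFFrame",
    "CohortSpec",
    "PatientScan",
    "Cohort",
    "diffuse_field",
    "regular_field",
    "simulate_rf_frame",
    "make_reference_frames",
    "make_cohort",
    "simulate_feature_table",
]

_DB20 = np.log(10.0) / 20.0


@dataclass
class ScattererField:
    """Point-scatterer medium over a rectangular (axial x lateral) extent.

    positions are (N, 2) arrays of (axial z, lateral x) in meters;
    ``effective_diameter`` may be a scalar or per-scatterer array (m).
    ``mean_spacing`` records the quasi-periodic axial spacing when the field
    was built with one (ground truth for SAS recovery), else None.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    extent: tuple[float, float, float, float]  # (z0, z1, x0, x1) in m
    number_density: float
    effective_diameter: float | np.ndarray = 50e-6
    mean_spacing: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("positions and amplitudes length mismatch")
        if self.positions.shape[0] == 0:
            raise ValueError("scatterer field is empty")
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.amplitudes)
        ):
            raise ValueError("non-finite scatterer data")
        z0, z1, x0, x1 = self.extent
        z, x = self.positions[:, 0], self.positions[:, 1]
        if z.min() < z0 - 1e-9 or z.max() > z1 + 1e-9:
            raise ValueError("scatterer axial positions outside field extent")
        if x.min() < x0 - 1e-9 or x.max() > x1 + 1e-9:
            raise ValueError("scatterer lateral positions outside field extent")
        if self.number_density <= 0:
            raise ValueError("number_density must be positive")

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]


@dataclass
class RFFrame:
    """One beamformed RF echo frame: samples[axial sample, scan line]."""

    samples: np.ndarray
    acquisition: AcquisitionSpec
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2D (axial sample x scan line)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]


def diffuse_field(
    extent: tuple[float, float, float, float],
    number_density: float,
    rng: np.random.Generator,
    effective_diameter: float = 50e-6,
    density_map=None,
) -> ScattererField:
    """Poisson-random diffuse scatterer field.

    ``density_map(z, x)`` optionally returns a relative density multiplier in
    (0, inf) used for position-dependent thinning/boosting (patchy media);
    the realized density is ``number_density * density_map``.  Amplitudes are
    standard normal (zero mean), giving fully developed, incoherent speckle
    whose band-averaged power is proportional to the local density.
    """
    z0, z1, x0, x1 = extent
    area = (z1 - z0) * (x1 - x0)
    if area <= 0:
        raise ValueError("degenerate field extent")
    peak = 1.0
    if density_map is not None:
        # rejection sampling against the peak multiplier on a probe grid
        zz = np.linspace(z0, z1, 64)
        xx = np.linspace(x0, x1, 32)
        peak = float(np.max(density_map(zz[:, None], xx[None, :])))
    n = rng.poisson(number_density * peak * area)
    z = rng.uniform(z0, z1, size=n)
    x = rng.uniform(x0, x1, size=n)
    if density_map is not None and n > 0:
        keep = rng.uniform(0, peak, size=n) < density_map(z, x)
        z, x = z[keep], x[keep]
    if z.size == 0:
        raise ValueError("density too low: no scatterers drawn")
    amps = rng.standard_normal(z.size)
    return ScattererField(
        positions=np.column_stack([z, x]),
        amplitudes=amps,
        extent=extent,
        number_density=number_density,
        effective_diameter=effective_diameter,
    )


def regular_field(
    extent: tuple[float, float, float, float],
    spacing: float,
    rng: np.random.Generator,
    line_pitch: float = 0.2e-3,
    jitter: float = 0.0,
    amplitude_jitter: float = 0.05,
    effective_diameter: float = 50e-6,
) -> ScattererField:
    """Quasi-periodic axial lattice of scatterers, one column per scan line.

    Each line carries scatterers at axial spacing ``spacing`` with a random
    per-line phase offset; ``jitter`` is the per-scatterer positional
    standard deviation (m).  The averaged power spectrum of such a medium is
    a frequency comb with tooth spacing c / (2 * spacing).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    z0, z1, x0, x1 = extent
    n_lines = max(1, int(round((x1 - x0) / line_pitch)))
    xs = x0 + (np.arange(n_lines) + 0.5) * line_pitch
    zs_all, xs_all = [], []
    for x in xs:
        offset = rng.uniform(0, spacing)
        z = np.arange(z0 + offset, z1, spacing)
        zs_all.append(z)
        xs_all.append(np.full(z.size, x))
    z = np.concatenate(zs_all)
    x = np.concatenate(xs_all)
    if jitter > 0:
        z = np.clip(z + rng.normal(0, jitter, z.size), z0, z1)
    amps = 1.0 + amplitude_jitter * rng.standard_normal(z.size)
    density = z.size / ((z1 - z0) * (x1 - x0))
    return ScattererField(
        positions=np.column_stack([z, x]),
        amplitudes=amps,
        extent=extent,
        number_density=density,
        effective_diameter=effective_diameter,
        mean_spacing=spacing,
    )


def simulate_rf_frame(
    field: ScattererField,
    pulse: PulseModel,
    acq: AcquisitionSpec,
    attenuation: float = 0.0,
    seed: int | None = None,
    noise_rel: float = 0.0,
    frame_id: str = "",
    n_samples: int | None = None,
) -> RFFrame:
    """Synthesize one RF frame from a scatterer field.

    Parameters
    ----------
    attenuation : float
        Attenuation coefficient alpha in dB/cm/MHz (package convention:
        power-spectrum loss 4 alpha f z dB from depth z), applied
        cumulatively with depth.
    noise_rel : float
        Additive white-noise amplitude relative to the RMS of the noiseless
        frame (electronic noise floor).
    seed : int
        Seeds the noise generator only; the deterministic part depends only
        on the field. Required when ``noise_rel > 0``.

    The frame always starts at depth 0 (transducer face); its axial length
    covers the field's far edge plus a pulse-length guard band.
    """
    if attenuation < 0:
        raise ValueError("attenuation must be non-negative")
    z0, z1, x0, x1 = field.extent
    n_lines = max(1, int(round((x1 - x0) / acq.line_pitch)))
    if n_samples is None:
        guard = 8 * pulse.sigma_t * acq.sound_speed / 2.0
        n_samples = int(np.ceil((z1 + guard) / acq.axial_step))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / acq.sampling_rate)
    base = pulse.spectrum(freqs) * (freqs / 1e6) ** 2  # pulse x Rayleigh amplitude

    z = field.positions[:, 0]
    x = field.positions[:, 1]
    line_idx = np.clip(((x - x0) / acq.line_pitch).astype(int), 0, n_lines - 1)
    t = 2.0 * z / acq.sound_speed
    a_eff = np.broadcast_to(
        np.asarray(field.effective_diameter, dtype=float), z.shape
    )

    # per-scatterer complex exponent: delay phase + attenuation + form factor,
    # all linear/quadratic in f -> one vectorized exp per line
    out = np.zeros((n_samples, n_lines))
    f = freqs[None, :]
    for li in np.unique(line_idx):
        sel = line_idx == li
        tk = t[sel][:, None]
        zk_cm = (z[sel] * 100.0)[:, None]
        ak = a_eff[sel][:, None]
        exponent = (
            -2j * np.pi * f * tk
            - _DB20 * 4.0 * attenuation * (f / 1e6) * zk_cm
            - 0.827 * (np.pi * f * ak / acq.sound_speed) ** 2 / 2.0
        )
        spec = (field.amplitudes[sel][:, None] * np.exp(exponent)).sum(axis=0)
        out[:, li] = np.fft.irfft(base * spec, n=n_samples)

    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        rms = np.sqrt(np.mean(out**2))
        out = out + noise_rel * rms * rng.standard_normal(out.shape)
    return RFFrame(samples=out, acquisition=acq, frame_id=frame_id)


def make_reference_frames(
    acq: AcquisitionSpec | None = None,
    pulse: PulseModel | None = None,
    seed: int = 0,
    n_frames: int = 5,
    extent: tuple[float, float, float, float] = (0.002, 0.024, 0.0, 0.0064),
    number_density: float = 4e8,
    effective_diameter: float = 10e-6,
) -> list[RFFrame]:
    """Tissue-mimicking reference phantom frames: dense diffuse scatterers,
    zero attenuation, small (spectrally flat) scatterers.

    At least 5 frames are generated so the reference spectrum is an average
    over many independent speckle realizations.
    """
    acq = acq or default_acquisition()
    pulse = pulse or default_pulse()
    if n_frames < 5:
        raise ValueError("need >= 5 reference frames for spectral averaging")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        fld = diffuse_field(extent, number_density, rng, effective_diameter)
        frames.append(
            simulate_rf_frame(fld, pulse, acq, attenuation=0.0, frame_id=f"ref{i}")
        )
    return frames


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic outcome-labeled cohort.

    Defaults emulate the clinical setting the package targets: 28 patients
    with eventual recurrence (label R) and 55 without (NR); per-class
    recurrence-free-survival hazards chosen so the R class has median time
    to event near 24 months while the NR class retains ~80% 5-year RFS;
    administrative censoring at the 69-month median follow-up.  The two
    classes differ in tissue architecture: the R class carries patchy
    spatial modulation of scatterer density (heterogeneous parametric maps),
    the NR class is uniform.
    """

    n_recurrence: int = 28
    n_non_recurrence: int = 55
    frames_per_patient: tuple[int, int] = (3, 7)
    hazard_rfs: dict = field(
        default_factory=lambda: {"R": 0.029, "NR": 0.0045}
    )  # events / month
    hazard_os: dict = field(default_factory=lambda: {"R": 0.0050, "NR": 0.0027})
    censor_time: float = 69.0  # months
    patch_contrast: dict = field(default_factory=lambda: {"R": 3.0, "NR": 1.0})
    patch_size: float = 1.5e-3  # m, correlation length of density patches
    base_density: float = 2e8  # scatterers / m^2
    scatterer_diameter: dict = field(
        default_factory=lambda: {"R": 80e-6, "NR": 80e-6}
    )
    sas_spacing: dict = field(default_factory=lambda: {"R": 0.45e-3, "NR": 0.45e-3})
    lattice_amplitude: float = 2.5  # quasi-periodic echo strength vs speckle
    extent: tuple[float, float, float, float] = (0.004, 0.020, 0.0, 0.0064)
    roi_margin: float = 1.5e-3  # m clearance between ROI ellipse and field edge
    attenuation: dict = field(default_factory=lambda: {"R": 0.7, "NR": 0.7})
    noise_rel: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recurrence < 2 or self.n_non_recurrence < 2:
            raise ValueError("need >= 2 patients per class")
        if min(self.hazard_rfs.values()) <= 0 or min(self.hazard_os.values()) <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be non-negative")


@dataclass
class PatientScan:
    """All frames and ROI masks for one patient, plus simulation ground truth."""

    patient_id: str
    frames: list
    rois: list
    ground_truth: dict


@dataclass
class Cohort:
    """Synthetic study cohort: per-patient scans and the outcomes table."""

    patients: list
    outcomes: pd.DataFrame
    spec: CohortSpec

    def scans(self) -> dict:
        return {p.patient_id: p for p in self.patients}


def _patchy_density_map(rng: np.random.Generator, extent, patch_size, contrast):
    """Smooth random patch field: density multiplier in [1, contrast]."""
    z0, z1, x0, x1 = extent
    nz = max(4, int(np.ceil((z1 - z0) / patch_size)) + 1)
    nx = max(4, int(np.ceil((x1 - x0) / patch_size)) + 1)
    knots = rng.standard_normal((nz, nx))

    def raw(z, x):
        fz = np.clip((np.asarray(z) - z0) / (z1 - z0), 0, 1) * (nz - 1)
        fx = np.clip((np.asarray(x) - x0) / (x1 - x0), 0, 1) * (nx - 1)
        iz = np.clip(fz.astype(int), 0, nz - 2)
        ix = np.clip(fx.astype(int), 0, nx - 2)
        wz, wx = fz - iz, fx - ix
        v = (
            knots[iz, ix] * (1 - wz) * (1 - wx)
            + knots[iz + 1, ix] * wz * (1 - wx)
            + knots[iz, ix + 1] * (1 - wz) * wx
            + knots[iz + 1, ix + 1] * wz * wx
        )
        # logistic squashing to [1, contrast]
        return 1.0 + (contrast - 1.0) / (1.0 + np.exp(-2.0 * v))

    # normalize to unit mean density so patchiness changes heterogeneity,
    # not the class-mean backscatter level
    zz = np.linspace(z0, z1, 48)
    xx = np.linspace(x0, x1, 24)
    mean = float(np.mean(raw(zz[:, None], xx[None, :])))

    def dmap(z, x):
        return raw(z, x) / mean

    return dmap


def _ellipse_roi(frame: RFFrame, extent, margin) -> np.ndarray:
    """Boolean ROI mask (sample x line) for an ellipse inscribed in the field."""
    acq = frame.acquisition
    z0, z1, x0, x1 = extent
    cz, cx = 0.5 * (z0 + z1), 0.5 * (x0 + x1)
    rz, rx = 0.5 * (z1 - z0) - margin, 0.5 * (x1 - x0) - margin
    zs = acq.depth_of_sample(np.arange(frame.n_samples))[:, None]
    xs = (x0 + (np.arange(frame.n_lines) + 0.5) * acq.line_pitch)[None, :]
    return ((zs - cz) / rz) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0


def _tissue_field(
    rng: np.random.Generator, spec: CohortSpec, label: str
) -> ScattererField:
    """Diffuse background + jittered quasi-periodic lattice for one frame."""
    contrast = spec.patch_contrast[label]
    dmap = (
        _patchy_density_map(rng, spec.extent, spec.patch_size, contrast)
        if contrast > 1.0
        else None
    )
    diam = spec.scatterer_diameter[label]
    diffuse = diffuse_field(
        spec.extent, spec.base_density, rng, effective_diameter=diam, density_map=dmap
    )
    lattice = regular_field(
        spec.extent,
        spacing=spec.sas_spacing[label],
        rng=rng,
        jitter=0.02e-3,
        effective_diameter=diam,
    )
    # lattice echoes above speckle so the comb is detectable in-band
    lat_amp = spec.lattice_amplitude * lattice.amplitudes * np.sign(
        rng.standard_normal(1)
    )
    return ScattererField(
        positions=np.vstack([diffuse.positions, lattice.positions]),
        amplitudes=np.concatenate([diffuse.amplitudes, lat_amp]),
        extent=spec.extent,
        number_density=spec.base_density,
        effective_diameter=diam,
        mean_spacing=lattice.mean_spacing,
    )


def make_cohort(
    spec: CohortSpec,
    acq: AcquisitionSpec | None = None,
    pulse: PulseModel | None = None,
) -> Cohort:
    """Generate a full labeled cohort: scans, ROIs and survival outcomes.

    Deterministic given ``spec`` (including its seed).  Each patient gets a
    random number of tumor-slice frames in ``frames_per_patient`` (emulating
    scans at regular 1 cm intervals through the tumor), an elliptical ROI,
    and exponential event times per endpoint truncated by administrative
    censoring at ``spec.censor_time``.
    """
    acq = acq or default_acquisition()
    pulse = pulse or default_pulse()
    root = np.random.SeedSequence(spec.seed)
    labels = ["R"] * spec.n_recurrence + ["NR"] * spec.n_non_recurrence
    patients, rows = [], []
    for i, (label, ss) in enumerate(zip(labels, root.spawn(len(labels)))):
        rng = np.random.default_rng(ss)
        pid = f"P{i:03d}"
        n_frames = int(rng.integers(spec.frames_per_patient[0], spec.frames_per_patient[1] + 1))
        frames, rois = [], []
        for j in range(n_frames):
            fld = _tissue_field(rng, spec, label)
            frame = simulate_rf_frame(
                fld,
                pulse,
                acq,
                attenuation=spec.attenuation[label],
                seed=int(rng.integers(2**31)),
                noise_rel=spec.noise_rel,
                frame_id=f"{pid}_f{j}",
            )
            frames.append(frame)
            rois.append(_ellipse_roi(frame, spec.extent, spec.roi_margin))
        # RFS event = recurrence or death, whichever first; OS event = death
        t_recur = rng.exponential(1.0 / spec.hazard_rfs[label])
        t_death = rng.exponential(1.0 / spec.hazard_os[label])
        t_rfs = min(t_recur, t_death)
        rows.append(
            {
                "patient_id": pid,
                "label": label,
                "time_rfs_months": min(t_rfs, spec.censor_time),
                "event_rfs": int(t_rfs <= spec.censor_time),
                "time_os_months": min(t_death, spec.censor_time),
                "event_os": int(t_death <= spec.censor_time),
            }
        )
        patients.append(
            PatientScan(
                patient_id=pid,
                frames=frames,
                rois=rois,
                ground_truth={
                    "label": label,
                    "attenuation_db_cm_mhz": spec.attenuation[label],
                    "scatterer_diameter_m": spec.scatterer_diameter[label],
                    "sas_spacing_m": spec.sas_spacing[label],
                    "patch_contrast": spec.patch_contrast[label],
                },
            )
        )
    outcomes = pd.DataFrame(rows)
    return Cohort(patients=patients, outcomes=outcomes, spec=spec)


# ---------------------------------------------------------------------------
# feature-level cohort synthesis (for classifier / statistics studies)


def simulate_feature_table(
    feature_names,
    n_recurrence: int = 28,
    n_non_recurrence: int = 55,
    effects: dict | None = None,
    seed: int = 0,
):
    """Draw a patient x feature table with optional class effects.

    Every feature is standard normal; ``effects`` maps feature names to the
    mean shift (in SD units) added to the recurrence class.  Returns
    ``(X, y)`` with ``X`` a DataFrame in catalog column order and ``y`` a
    Series of {"R", "NR"} labels.  This is the controlled substrate for
    classifier and univariate-statistics studies where the map-level
    generator's effects would be confounded.
    """
    rng = np.random.default_rng(seed)
    names = list(feature_names)
    n = n_recurrence + n_non_recurrence
    X = rng.standard_normal((n, len(names)))
    y = np.array(["R"] * n_recurrence + ["NR"] * n_non_recurrence)
    for name, shift in (effects or {}).items():
        j = names.index(name)
        X[y == "R", j] += shift
    idx = [f"P{i:03d}" for i in range(n)]
    return (
        pd.DataFrame(X, columns=names, index=idx),
        pd.Series(y, index=idx, name="label"),
    )
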