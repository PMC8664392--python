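"""Scan-container and table I/O.

One HDF5 file per patient: groups ``/frames/<id>/rf`` (integer RF array,
quantized to the acquisition bit depth at write time with a stored scale
factor) and ``/frames/<id>/roi`` (boolean mask in sample x line
coordinates); the acquisition metadata lives in file-level attributes.
Simulation ground truth goes to a JSON sidecar.  Cohort outcomes are a
plain CSV (patient_id, label, RFS/OS time and event columns).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .simulate import Cohort, PatientScan, RFFrame

__all__ = [
    "write_patient_scan",
    "read_patient_scan",
    "write_cohort",
    "read_cohort_scans",
    "write_outcomes",
    "read_outcomes",
]

OUTCOME_COLUMNS = [
    "patient_id",
    "label",
    "time_rfs_months",
    "event_rfs",
    "time_os_months",
    "event_os",
]


def _acq_attrs(acq: AcquisitionSpec) -> dict:
    return {
        "sampling_rate": acq.sampling_rate,
        "center_frequency": acq.center_frequency,
        "band_low": acq.analysis_band[0],
        "band_high": acq.analysis_band[1],
        "sound_speed": acq.sound_speed,
        "bit_depth": acq.bit_depth,
        "line_pitch": acq.line_pitch,
    }


def _acq_from_attrs(attrs) -> AcquisitionSpec:
    return AcquisitionSpec(
        sampling_rate=float(attrs["sampling_rate"]),
        center_frequency=float(attrs["center_frequency"]),
        analysis_band=(float(attrs["band_low"]), float(attrs["band_high"])),
        sound_speed=float(attrs["sound_speed"]),
        bit_depth=int(attrs["bit_depth"]),
        line_pitch=float(attrs["line_pitch"]),
    )


def write_patient_scan(scan: PatientScan, path) -> Path:
    """Write one patient's frames/ROIs to HDF5 + ground-truth JSON sidecar.

    RF samples are quantized to the acquisition bit depth (symmetric
    mid-rise, 90% full scale) and stored as integers with the scale in a
    dataset attribute, honoring the ADC-resolution contract.
    """
    path = Path(path)
    acq = scan.frames[0].acquisition
    dtype = np.int16 if acq.bit_depth == 16 else np.int8
    full = 2 ** (acq.bit_depth - 1) - 1
    with h5py.File(path, "w") as h5:
        h5.attrs.update(_acq_attrs(acq))
        h5.attrs["patient_id"] = scan.patient_id
        grp = h5.create_group("frames")
        for frame, roi in zip(scan.frames, scan.rois):
            g = grp.create_group(frame.frame_id)
            peak = float(np.max(np.abs(frame.samples))) or 1.0
            scale = 0.9 * full / peak
            q = np.clip(np.round(frame.samples * scale), -full, full).astype(dtype)
            ds = g.create_dataset("rf", data=q)
            ds.attrs["scale"] = scale
            g.create_dataset("roi", data=np.asarray(roi, dtype=bool))
    path.with_suffix(".json").write_text(
        json.dumps(scan.ground_truth, indent=2, sort_keys=True)
    )
    return path


def read_patient_scan(path) -> PatientScan:
    """Read a patient scan container written by :func:`write_patient_scan`."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        acq = _acq_from_attrs(h5.attrs)
        pid = str(h5.attrs["patient_id"])
        frames, rois = [], []
        for fid in sorted(h5["frames"]):
            g = h5["frames"][fid]
            rf = g["rf"][()].astype(float) / float(g["rf"].attrs["scale"])
            frames.append(RFFrame(samples=rf, acquisition=acq, frame_id=fid))
            rois.append(g["roi"][()].astype(bool))
    sidecar = path.with_suffix(".json")
    gt = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return PatientScan(patient_id=pid, frames=frames, rois=rois, ground_truth=gt)


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write every patient container plus the outcomes CSV into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        write_patient_scan(p, directory / f"{p.patient_id}.h5")
    write_outcomes(cohort.outcomes, directory / "outcomes.csv")
    return directory


def read_cohort_scans(directory) -> list[PatientScan]:
    directory = Path(directory)
    return [read_patient_scan(p) for p in sorted(directory.glob("*.h5"))]


def write_outcomes(outcomes: pd.DataFrame, path) -> Path:
    path = Path(path)
    outcomes[OUTCOME_COLUMNS].to_csv(path, index=False)
    return path


def read_outcomes(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"outcomes file not found: {path}")
    df = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"outcomes file lacks columns: {sorted(missing)}")
    return df
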