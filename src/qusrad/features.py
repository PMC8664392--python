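"""The 95-feature radiomics catalog and patient-level feature assembly.

Three tiers:

* 7 spectral (first-order): MBF, SS, SI, SAS, ASD, AAC averaged over the
  sub-ROI maps, plus the frame-level ACE;
* 24 texture (QUS-Tex1): CON/COR/ENE/HOM of each of the 6 parametric maps
  (no map exists for ACE);
* 64 texture-derivative (QUS-Tex1-Tex2): the four GLCM features of each of
  the 16 eligible texture maps ({MBF, SI, ASD, AAC} x {CON, COR, ENE, HOM};
  SS and SAS texture maps are excluded).

Per-patient vectors are the unweighted mean of each feature over the
patient's tumor-slice frames; frames where a feature is invalid are
dropped from that feature's average only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import SpectralConfig, build_parametric_maps
from .texture import (
    DERIVATIVE_PARAMS,
    TEXTURE_FEATURE_NAMES,
    GLCMError,
    GLCMSpec,
    texture_derivative,
    texture_map_of,
    texture_of_map,
)

__all__ = [
    "SPECTRAL_NAMES",
    "FeatureCatalog",
    "FeatureExtractionError",
    "feature_catalog",
    "extract_frame_features",
    "extract_patient_features",
    "cohort_feature_matrix",
]

SPECTRAL_NAMES = ("MBF", "SS", "SI", "SAS", "ASD", "AAC", "ACE")
_MAP_PARAMS = ("MBF", "SS", "SI", "SAS", "ASD", "AAC")


class FeatureExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, tiered catalog of the radiomics feature names."""

    names: tuple[str, ...]
    tiers: dict

    @property
    def spectral(self) -> list[str]:
        return [n for n in self.names if self.tiers[n] == "spectral"]

    @property
    def texture(self) -> list[str]:
        return [n for n in self.names if self.tiers[n] == "texture"]

    @property
    def derivative(self) -> list[str]:
        return [n for n in self.names if self.tiers[n] == "derivative"]

    def pool(self, which: str) -> list[str]:
        """Feature pools used by the classification protocol.

        ``"qus_tex1"`` — first + second order (spectral + texture);
        ``"all"`` — all three tiers.
        """
        if which == "qus_tex1":
            return self.spectral + self.texture
        if which == "all":
            return list(self.names)
        raise ValueError(f"unknown pool {which!r}")


def feature_catalog() -> FeatureCatalog:
    """The deterministic 7 + 24 + 64 = 95 feature catalog."""
    names: list[str] = list(SPECTRAL_NAMES)
    tiers = {n: "spectral" for n in names}
    for p in _MAP_PARAMS:
        for t in TEXTURE_FEATURE_NAMES:
            n = f"{p}-{t}"
            names.append(n)
            tiers[n] = "texture"
    for p in DERIVATIVE_PARAMS:
        for t1 in TEXTURE_FEATURE_NAMES:
            for t2 in TEXTURE_FEATURE_NAMES:
                n = f"{p}-{t1}-{t2}"
                names.append(n)
                tiers[n] = "derivative"
    return FeatureCatalog(names=tuple(names), tiers=tiers)


def extract_frame_features(
    frame,
    roi_mask,
    reference_frames,
    spectral_config: SpectralConfig | None = None,
    glcm_spec: GLCMSpec | None = None,
    neighborhood: int = 5,
) -> dict[str, float]:
    """All 95 features for one frame; NaN marks per-frame invalid features."""
    spectral_config = spectral_config or SpectralConfig()
    glcm_spec = glcm_spec or GLCMSpec()
    maps, ace = build_parametric_maps(frame, roi_mask, reference_frames, spectral_config)
    out: dict[str, float] = {}
    for p in _MAP_PARAMS:
        out[p] = maps[p].mean()
    out["ACE"] = float(ace)
    for p in _MAP_PARAMS:
        try:
            tf = texture_of_map(maps[p], glcm_spec)
            for t, v in tf.as_dict().items():
                out[f"{p}-{t}"] = v
        except (GLCMError, ValueError):
            for t in TEXTURE_FEATURE_NAMES:
                out[f"{p}-{t}"] = np.nan
    tmaps = {}
    for p in DERIVATIVE_PARAMS:
        for t, tm in texture_map_of(maps[p], glcm_spec, neighborhood).items():
            tmaps[(p, t)] = tm
    try:
        out.update(texture_derivative(tmaps, glcm_spec))
    except (GLCMError, ValueError):
        for p in DERIVATIVE_PARAMS:
            for t1 in TEXTURE_FEATURE_NAMES:
                for t2 in TEXTURE_FEATURE_NAMES:
                    out[f"{p}-{t1}-{t2}"] = np.nan
    return out


def extract_patient_features(
    scan,
    reference_frames,
    spectral_config: SpectralConfig | None = None,
    glcm_spec: GLCMSpec | None = None,
    neighborhood: int = 5,
) -> pd.Series:
    """Patient feature vector: per-feature mean over the tumor-slice frames.

    A feature invalid on some frames is averaged over the remaining frames;
    a feature invalid on *every* frame raises, naming feature and patient.
    """
    if len(scan.frames) == 0:
        raise FeatureExtractionError(f"patient {scan.patient_id} has no frames")
    catalog = feature_catalog()
    records = [
        extract_frame_features(
            fr, roi, reference_frames, spectral_config, glcm_spec, neighborhood
        )
        for fr, roi in zip(scan.frames, scan.rois)
    ]
    df = pd.DataFrame(records, columns=list(catalog.names))
    means = df.mean(axis=0, skipna=True)
    missing = means.index[means.isna()]
    if len(missing):
        raise FeatureExtractionError(
            f"feature(s) {list(missing)} invalid on all frames of patient "
            f"{scan.patient_id}"
        )
    means.name = scan.patient_id
    return means


def cohort_feature_matrix(
    cohort,
    reference_frames,
    spectral_config: SpectralConfig | None = None,
    glcm_spec: GLCMSpec | None = None,
    neighborhood: int = 5,
) -> pd.DataFrame:
    """Patients x 95 feature matrix in catalog column order."""
    rows = [
        extract_patient_features(
            p, reference_frames, spectral_config, glcm_spec, neighborhood
        )
        for p in cohort.patients
    ]
    return pd.DataFrame(rows)
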