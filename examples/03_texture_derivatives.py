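"""From parametric maps to the 95-feature radiomics vector.

Simulates one patchy (heterogeneous) tumor frame, extracts the 7 spectral
features, the 24 GLCM texture features of the parametric maps, and the 64
texture-derivative features (GLCM of the texture maps), and prints the
tier structure of the catalog.
"""

import numpy as np

from qusrad import (
    CohortSpec,
    default_acquisition,
    default_pulse,
    extract_frame_features,
    feature_catalog,
    make_cohort,
    make_reference_frames,
)

acq, pulse = default_acquisition(), default_pulse()
spec = CohortSpec(n_recurrence=2, n_non_recurrence=2, frames_per_patient=(1, 1), seed=3)
cohort = make_cohort(spec)
patient = cohort.patients[0]  # an "R"-class patient: patchy density field
z1 = max(fr.n_samples for p in cohort.patients for fr in p.frames)
refs = make_reference_frames(acq, pulse, seed=4,
                             extent=(0.002, (z1 + 8) * acq.axial_step, 0.0, 0.0064))

feats = extract_frame_features(patient.frames[0], patient.rois[0], refs)
cat = feature_catalog()
print(f"catalog: {len(cat.names)} features = {len(cat.spectral)} spectral + "
      f"{len(cat.texture)} texture + {len(cat.derivative)} texture-derivative")
print("\nspectral tier:")
for n in cat.spectral:
    print(f"  {n:4s} = {feats[n]:.4g}")
print("\na few texture features (heterogeneity of the maps):")
for n in ("MBF-CON", "MBF-COR", "AAC-ENE", "ASD-HOM"):
    print(f"  {n:8s} = {feats[n]:.4f}")
print("\na few texture-derivative features (structure of the heterogeneity):")
for n in ("SI-COR-CON", "SI-COR-HOM", "AAC-CON-CON", "MBF-ENE-HOM"):
    print(f"  {n:12s} = {feats[n]:.4f}")
# CON grows with abrupt level changes between neighboring sub-ROIs; ENE and
# HOM are large for uniform maps. The derivative tier applies the same
# statistics to maps OF those statistics - third-order structure.
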