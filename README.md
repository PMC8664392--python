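# qusrad

Quantitative-ultrasound (QUS) radiomics for recurrence-risk stratification
on raw radiofrequency (RF) data.

Clinical B-mode ultrasound throws away the raw echo signal; QUS keeps it.
The spectrum of the beamformed RF signal, calibrated against a
tissue-mimicking reference phantom, carries information about tissue
microstructure — scatterer size, concentration, spacing and attenuation —
that correlates with tumor biology. This package implements a complete
QUS-radiomics analysis chain of the kind used to predict disease
recurrence in locally advanced breast cancer from a pre-treatment scan:

1. **Spectral parameters** (per 2 mm sliding sub-ROI, 94% overlap,
   4–9 MHz band): mid-band fit (MBF), spectral slope (SS), spectral
   intercept (SI) from the OLS line fit to the normalized dB spectrum;
   spacing among scatterers (SAS) from the spectral comb periodicity,
   SAS = c/(2Δf); acoustic scatterer diameter (ASD) and average acoustic
   concentration (AAC) from a spherical-Gaussian form-factor fit
   10·log₁₀(C·f⁴·exp(−0.827(ka/2)²)) + A; and an attenuation
   coefficient estimate (ACE) by the spectral-difference method, used to
   depth-correct the spectra and kept as a feature.
2. **Texture (QUS-Tex¹)**: gray-level co-occurrence matrix (GLCM)
   statistics — contrast, correlation, energy, homogeneity — of each of
   the six parametric maps, symmetric and averaged over the 0°/45°/90°/135°
   angles (24 features).
3. **Texture derivatives (QUS-Tex¹-Tex²)**: texture maps are regenerated
   from local GLCM features and the GLCM analysis is applied *again* to
   those maps, yielding 64 third-order features that capture the spatial
   organization of heterogeneity itself. Total catalog: 7 + 24 + 64 = 95.
4. **Statistics and classification**: per-feature Shapiro-Wilk-routed
   t / Mann-Whitney comparisons; class-balanced subset construction;
   greedy forward selection (max 3 features) with KNN and RBF-SVM scored
   by leave-one-out cross-validation; sensitivity / specificity /
   accuracy / AUC with recurrence as the positive class.
5. **Survival**: Kaplan-Meier product-limit curves with Greenwood
   variance and the two-group log-rank test, applied to the
   classifier-predicted recurrence vs non-recurrence groups for
   recurrence-free and overall survival.

Because clinical RF scans are rarely shareable, the package ships a
ground-truthed synthetic RF generator (`qusrad.simulate`): point-scatterer
media rendered per scan line in the frequency domain with exact
fractional delays, Rayleigh × form-factor scattering, depth-cumulative
frequency-dependent attenuation, reference phantoms, tumor ROI masks, and
outcome-labeled cohorts whose classes differ in map *heterogeneity*
(patchy vs uniform scatterer density) rather than first-order means.
Every estimator is validated against this generator's known truth.

## Worked example

A controlled 83-patient cohort (28 recurrence / 55 non-recurrence, 95
catalog features) with the class effect planted only in the
texture-derivative feature `SI-COR-CON`:

```python
from qusrad import ClassifierConfig, feature_catalog, run_paper_protocol
from qusrad.simulate import simulate_feature_table

cat = feature_catalog()
X, y = simulate_feature_table(cat.names, 28, 55,
                              effects={"SI-COR-CON": 1.8}, seed=0)
reports = run_paper_protocol(X, y, cat, ClassifierConfig(seed=0))
for (pool, kind), rep in sorted(reports.items()):
    print(pool, kind, rep.summary())
```

prints (`examples/04_classification.py`):

```
[knn | pool=all]      selected: SI-COR-CON, MBF-ENE
  sensitivity 78.6%  specificity 89.1%  accuracy 85.5%  AUC 0.891
[svm-rbf | pool=all]  selected: SI-COR-CON, SI-HOM-HOM, ASD-COR-COR
  sensitivity 82.1%  specificity 89.1%  accuracy 86.7%  AUC 0.886
[knn | pool=qus_tex1] selected: SI-COR, SI-HOM, SAS-HOM
  sensitivity 57.1%  specificity 78.2%  accuracy 71.1%  AUC 0.703
[svm-rbf | pool=qus_tex1] selected: MBF-ENE, SI-COR
  sensitivity 0.0%   specificity 83.6%  accuracy 55.4%  AUC 0.589
```

The first+second-order pool cannot see the planted third-order effect and
hovers near chance, while selection from all 95 features finds
`SI-COR-CON` and reaches ~86% LOOCV accuracy — the qualitative signature
of texture-derivative radiomics. The other scripts in `examples/` walk
through RF simulation, parametric maps, the 95-feature extraction,
survival analysis and the end-to-end pipeline (also available as the
`qusrad` command-line tool with `simulate` / `extract` / `compare` /
`classify` / `survive` / `all` subcommands).

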