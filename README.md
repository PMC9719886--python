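# dectrod

Lesion–node similarity of quantitative dual-energy CT (DECT) parameters for
predicting axillary lymph node metastasis in breast cancer.

## The problem

Staging breast cancer requires knowing whether axillary lymph nodes harbour
metastasis. Raw quantitative DECT parameters of a node — attenuation of the
40- and 70-keV virtual monochromatic images (HU), iodine and water
concentration (IC/WC, mg/cm³), effective atomic number (Eff-Z) — do carry
signal, but they depend on the scanner, the protocol and the contrast
injection. Because metastatic node tissue is progressively replaced by
tumour, a metastatic node should *resemble its own primary lesion*
spectrally, and a within-patient similarity statistic is largely free of
those acquisition factors.

`dectrod` implements that statistic and the statistical workflow that
evaluates it, for methodologists and imaging researchers who want to study
or extend similarity-based nodal staging on tabular cohorts, parameter maps,
or simulated data.

## The model

For each ROI the spectral slope is

    λHU = (attenuation at 40 keV − attenuation at 70 keV) / 30   [HU/keV]

and IC, WC and Eff-Z are normalized by the same quantities measured in the
aorta. The similarity of node to primary lesion is the **rate of difference**

    ROD = |node value − lesion value| / lesion value

computed per parameter (0 = identical). The workflow then mirrors a
diagnostic-accuracy study: Mann–Whitney / Fisher / chi-squared group
comparisons, Spearman lesion–node correlation per group, univariable
screening at P < 0.001, forward logistic regression (ROD terms entering as
`10·(1 − ROD)` so that greater similarity means higher metastasis odds), and
ROC analysis with Youden-optimal thresholds, in the full cohort and in the
small-node (shortest diameter < 5 mm) subgroup where size criteria fail.

Because no patient-level data are publicly available for this problem, the
package ships a first-class synthetic cohort generator: a per-group
latent-Gaussian copula (single shared factor) calibrated to the published
group marginals, morphology and pathology proportions, and the published
lesion–node rank-correlation contrast (≈0.65 in metastatic pairs, ≈0.14
otherwise). See `docs/methods.md` for the model, its parameters and its
limitations.

## Worked example

```python
from dectrod import SpectralMeasurement, build_similarity_profile

node = SpectralMeasurement(att40=288, att70=108, ic=31.8, wc=1039, effz=9.34)
lesion = SpectralMeasurement(att40=284, att70=112, ic=30.6, wc=1030, effz=9.28)
print(f"{node.lambda_hu:.1f} {lesion.lambda_hu:.1f}")
profile = build_similarity_profile(lesion, node)
print({k: round(v, 3) for k, v in profile.as_dict().items()})
```

prints

```
6.0 5.7
{'rod_att40': 0.014, 'rod_att70': 0.036, 'rod_lambda': 0.047,
 'rod_ic': 0.039, 'rod_wc': 0.009, 'rod_effz': 0.006}
```

— node slopes of 6.0 vs 5.7 HU/keV and RODs near zero: this node's spectral
profile is nearly identical to its primary lesion, the signature of
metastatic involvement. A non-metastatic pair gives RODs an order of
magnitude larger (run `examples/similarity_worked_example.py`).

At cohort scale (`examples/full_pipeline.py`, n = 2,000 synthetic patients):

```
full-cohort AUC, ROD of attenuation at 40 keV: 0.79
full-cohort AUC, raw attenuation at 40 keV:    0.77
```

the similarity marker out-discriminates the raw node parameter, and in the
multivariable model (`examples/modeling_and_roc.py`) the transformed ROD of
40-keV attenuation stays independently associated with metastasis
(OR ≈ 2.1 per similarity unit) while raw attenuation contributes almost
nothing (OR ≈ 1.02 per HU).

The `examples/` directory has one short script per capability (similarity,
simulation, ROI extraction from parameter maps, group comparison, modeling
and ROC, the full pipeline). The same stages are available from the shell:

```
dectrod simulate --n 137 --seed 1 --out cohort.csv
dectrod derive --in cohort.csv --out derived.csv
dectrod roc --in derived.csv --out roc.csv
dectrod report --seed 1 --n 10000 --out report.json
```

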