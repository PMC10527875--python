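# dsmri — domain-shift quantification for multi-center structural MRI

Multi-site neuroimaging studies pool scans from different scanners, field
strengths and protocols. The resulting *domain shift* — systematic,
non-biological differences between sites — silently degrades any analysis
trained across sites, and harmonization pipelines need a way to check
whether they actually removed it. `dsmri` is that check: an unsupervised,
no-reference toolkit for neuroimaging researchers and MRI quality-control
engineers that answers *how much does acquisition site structure my data,
and through which image properties?*

## How it works

Each 3-D volume (NIfTI, any of T1w/T2w/FLAIR, raw or preprocessed) is cut
into 2-D slices along the axial, sagittal and coronal planes. Per slice, a
foreground/background partition is detected (Otsu-based) and **22
image-quality features** are computed, then averaged over all retained
slices into one vector per scan:

| family | features |
|---|---|
| spatial | MEAN, RNG, VAR = σ²_F, CV = σ_F/μ_F, PSNR, SNR1 = σ_F/σ_B, SNR2 = μ_FP/σ_B, CNR, CJV = (σ_F+σ_B)/\|μ_F−μ_B\|, EFC |
| frequency | SNRF (low/high spectral power, dB), LFR, HFR (mean √\|FFT\| after low-/high-pass) |
| wavelet | WCS, WQS, WCE (one-level 2-D DWT, Coiflet) |
| texture | GLCM Contrast, Dissimilarity, ASM, Homogeneity, Correlation, Energy |

Domain shift between sites a and b is then measured four ways:

* **MMD²** = ‖E[ϕ(xₐ)] − E[ϕ(x_b)]‖²_H, estimated as
  mean K_aa + mean K_bb − 2 mean K_ab with an RBF kernel and
  median-heuristic bandwidth on standardized features;
* **domain-classification accuracy** of a linear SVM and a 500-tree random
  forest (stratified 5-fold CV) predicting the site label — near 1.0 means
  strong shift, near chance means none;
* **feature-importance ranking** from the random forest, pointing at the
  image properties that carry the shift;
* **t-SNE / UMAP embeddings** of the feature table for visual inspection.

A synthetic multi-site phantom generator (two-shell ellipsoid plus
scanner-profile effects: noise, gamma contrast, bias field, PSF smoothing,
voxel size) makes the whole pipeline testable end to end with no data
download. See `docs/methods.md` for definitions, conventions and
limitations.

## Worked example

```python
from dsmri import (ScannerProfile, generate_multisite_cohort,
                   extract_features, analyze_shift)

profiles = [
    ScannerProfile("siteA", noise_sd=5.0,  contrast_gamma=1.0, smoothing_fwhm=1.0),
    ScannerProfile("siteB", noise_sd=15.0, contrast_gamma=1.5, smoothing_fwhm=2.5),
]
volumes, labels = generate_multisite_cohort(profiles, n_per_site=10,
                                            shape=(48, 48, 48), seed=42)
table = extract_features(volumes, labels=labels)
report = analyze_shift(table, "site", seed=42, embed_methods=("tsne",))
print(report.pairwise_mmd.round(3))
for name, acc in report.accuracies.items():
    print(f"{name} 5-fold accuracy: {acc:.2f}")
print("top-5 features:", [f for f, _ in report.importance[:5]])
```

prints

```
       siteA  siteB
siteA  0.000  0.657
siteB  0.657  0.000
svm_linear 5-fold accuracy: 1.00
random_forest 5-fold accuracy: 1.00
top-5 features: ['PSNR', 'Dissimilarity', 'SNR1', 'Contrast', 'SNRF']
```

The two simulated scanners differ in noise, contrast and smoothing; both
classifiers separate them perfectly (strong shift), the between-site MMD²
is far above zero, and the most shift-carrying features are noise- and
texture-related — matching the injected differences. On a harmonized
dataset you would instead expect accuracies near 0.5 and an MMD² close to
the split-half value of a single site.

The same workflow is available from the shell:

```sh
dsmri simulate --sites 3 --n-per-site 30 --seed 42 --out cohort/
dsmri extract  --input-dir cohort/ --labels cohort/labels.csv --output features.csv
dsmri analyze  --features features.csv --label-col site --out report/
```

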