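# Methods

## Problem and approach

Multi-center structural MRI studies inherit systematic, non-biological
differences between acquisition sites — scanner vendor, model, field
strength, reconstruction filtering, resolution, protocol. This *domain
shift* degrades any model trained across sites and is what harmonization
methods try to remove. `dsmri` quantifies the shift without any reference
image: each scan is reduced to 22 no-reference image-quality features, and
shift is then measured in that feature space by four complementary
instruments — kernel two-sample distance (MMD), domain-classification
accuracy, random-forest feature importance, and 2-D embeddings.

The premise is that image-quality statistics are fingerprints of the
acquisition rather than of the subject: noise level, contrast scale,
spatial-frequency content and texture regularity track the scanner and
protocol, so scans from the same site cluster in feature space even when
the anatomy differs.

## Per-slice features

Features are computed on 2-D slices of the (canonically reoriented) volume
in all three anatomical planes. Each slice is first partitioned into
foreground F (anatomy) and background B (air) — see *Foreground detection*
below. With μ the mean, σ the population standard deviation, H×W the slice
size:

**Spatial domain.**
MEAN, RNG = max−min and VAR = σ²_F of the foreground intensities;
CV = σ_F/μ_F; CJV = (σ_F+σ_B)/|μ_F−μ_B|;
SNR1 = σ_F/σ_B; SNR2 = μ_FP/σ_B; CNR = (μ_FP−μ_BP)/σ_BP, where FP and BP
are seeded random 5×5 patches of foreground and of the air region;
PSNR = 10·log₁₀(max(F)²/MSE), with the MSE taken over foreground pixels
against the 5×5 median-filtered slice as denoised reference;
EFC = −Σⱼ (xⱼ/x_max)·ln(xⱼ/x_max) over all H·W pixels, x_max = √(Σxⱼ²),
normalized by its maximum √N·ln√N so a uniform slice scores exactly 1.

**Frequency domain** (on the background-zeroed rectangular slice).
SNRF = 10·log₁₀(P_signal/P_noise), where P_signal is the squared-magnitude
spectral power within 0.25·r_max of the centred DC bin and P_noise the
remainder (the 0.25 radius split is a package convention, configurable);
LFR and HFR are the mean of √|FFT| after convolving with the 3×3 binomial
low-pass kernel [[1,2,1],[2,4,2],[1,2,1]]/16, respectively the 3×3
Laplacian [[−1,−1,−1],[−1,8,−1],[−1,−1,−1]], both with reflect padding.

**Wavelet domain.** One-level 2-D DWT (first-order Coiflet by default) in
periodization mode, so orthonormal wavelets satisfy Parseval exactly. Over
the pooled four subbands: WCS = mean magnitude of the coefficients at or
above the mean magnitude (ties significant); WQS = Σ magnitudeᵢ·cos(phaseᵢ),
which for a real transform is the signed coefficient sum; WCE = mean
absolute coefficient. A real DWT has phases only in {0, π}; WQS would need
a complex (e.g. dual-tree) transform to carry genuine phase information.

**Texture domain.** Foreground intensities are linearly quantized to 64
grey levels (background gets an ignore label); co-occurrences are counted
at distance 1 along 0°/45°/90°/135°, symmetrized, normalized per angle and
averaged. From the resulting matrix P: Contrast = Σ(i−j)²P,
Dissimilarity = Σ|i−j|P, ASM = ΣP², Homogeneity = ΣP/(1+(i−j)²),
Correlation = Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ) (defined as 1 when σᵢσⱼ = 0: a
constant image is perfectly self-correlated), Energy = √ASM.

Intensities are used exactly as stored — no rescaling before extraction —
because scanner-dependent intensity scale is part of the signal being
measured; LFR/HFR/WQS/WCE deliberately scale with it.

## Foreground detection and the air region

The detector is: Otsu threshold estimated on a σ=1 px Gaussian-smoothed
copy of the slice, applied to the *original* slice; 3×3 binary closing;
largest connected component; hole filling. Estimating the threshold on the
smoothed copy stabilises it under noise; applying it to the original keeps
the boundary where the data put it (thresholding the smoothed slice drags
a ring of background into the foreground, because Otsu lands low in the
smoothing ramp when class sizes are unbalanced). A constant bright slice
is all foreground; a blank slice has empty foreground and is flagged
unusable.

σ_B and the background patch are estimated on the *air region*: the
background eroded by an 8-pixel guard band around the foreground, wide
enough to cover ~3 standard deviations of a 4 mm FWHM PSF at 1 mm voxels.
Without the guard, partial-volume and PSF-tail pixels below the threshold
keep σ_B > 0 even on skull-stripped volumes whose air is identically
zero, and the noise features would never be flagged unavailable there.

## Missing values

A feature whose precondition fails on a slice (empty region, vanishing
denominator, no admissible patch window) is recorded as missing, never as
a silent NaN of unknown origin; a PSNR with zero MSE is an infinity flag
treated as missing by aggregation. At analysis time missing entries are
imputed by the per-feature median; a feature missing on every scan (e.g.
SNR1/SNR2/CNR on skull-stripped data) standardizes to a constant zero
column, which removes it from every distance and classifier.

## From slices to scans

Per plane, slices whose foreground covers less than 1% of pixels are
excluded (near-empty edge slices destabilize the statistics). The
scan-level value of each feature is the unweighted mean over all retained
slices of all three planes, ignoring missing per-slice values. This keeps
the scan representation exactly 22-dimensional rather than concatenating
planes. Slices are taken in voxel space; no resampling to isotropic
spacing is performed, so voxel-size differences remain visible to the
features (intentionally — resolution is an acquisition parameter).

Patch randomness is seeded per (global seed, scan id, plane, slice index),
so extraction is bit-reproducible and independent of processing order.

## Shift measures

All analyses run on standardized features: median imputation, then
per-feature z-score with population SD (constant columns → 0).

**MMD.** Biased (V-statistic) squared maximum mean discrepancy,
mean K_aa + mean K_bb − 2 mean K_ab, with RBF kernel
k(x,y) = exp(−‖x−y‖²/2h²) and h the median pairwise distance of the pooled
sample (median heuristic), clipped at zero against float error. Kernel,
bandwidth and feature scaling are conventions; absolute MMD magnitudes are
therefore only comparable within one configuration, and the meaningful
quantity is a ratio — e.g. between-site MMD against the split-half MMD of
a single site, which estimates the value expected from sampling noise
alone.

**Domain classification.** Stratified 5-fold cross-validated mean accuracy
of a linear SVM (C = 1) and a 500-tree random forest predicting the site
label, all randomness seeded. High accuracy = strong shift; chance = none.

**Feature importance.** Impurity-based importances of one seeded 500-tree
forest fit on the full table, normalized to sum 1 and ranked. Caveat,
learned the hard way on synthetic data: when many features individually
separate the domains perfectly, impurity importance is near-uniform among
them and the ordering degenerates into tie-breaking; rankings are
mechanistically interpretable only below that saturation regime.

**Embeddings.** t-SNE (perplexity 30, PCA init; perplexity auto-reduced to
(n−1)/3 for small cohorts) and UMAP (n_neighbors 15, min_dist 0.1),
deterministic for a fixed seed.

## Synthetic multi-site cohorts

The phantom is a centered two-shell ellipsoid (bright core, dimmer shell,
semi-axes ≈ ¼ of each dimension) on a dark background — deliberately not a
brain, so masks, volumes and noise levels have analytic ground truth. A
`ScannerProfile` injects site-level effects, in order: gamma contrast
transform of the normalized tissue intensity, multiplicative low-order
polynomial bias field, additive Gaussian noise, then a Gaussian PSF of the
given FWHM applied to the noisy image. Applying the PSF after the noise
models reconstruction-side smoothing, which attenuates acquired noise
exactly as a smoother protocol does; a profile with FWHM 0 has background
SD equal to `noise_sd` exactly.

Subject-level (within-site) variability: 3% multiplicative jitter of base
intensity and semi-axes, plus a smooth per-volume random texture field
(10% amplitude, σ = 4 voxels) modulating the tissue. The texture term is
essential: without it all volumes of a site are nearly identical, every
feature separates sites perfectly, and importance rankings degenerate (see
caveat above) — unlike real cohorts, where anatomy dominates within-site
variance while air-based noise metrics track the scanner. Per-volume
randomness is keyed by (seed, site, index), so adding a site never
perturbs existing volumes. `skull_strip=True` zeroes all voxels outside
the ellipsoid after noise, emulating skull-stripped input.

Default profile (site-level units): base intensity 200 (arbitrary),
noise SD 5, gamma 1.0, FWHM 1.0 mm, bias amplitude 0.1, voxel 1.0 mm
isotropic — a clean, mildly filtered 3 T-like protocol.

What the phantom does **not** model: anatomy, Rician magnitude statistics
(noise is Gaussian and unclipped), k-space sampling, motion/ghosting,
multi-coil inhomogeneity beyond the polynomial bias. Passing the phantom
experiments therefore shows the pipeline detects *injected* acquisition
differences; it does not certify performance on any particular clinical
dataset.

## Canonical experiments and problem sizes

`dsmri.experiments` fixes the validation conditions (64³ volumes; sizes
chosen to run on one CPU in minutes while keeping estimates stable):

* three vendor-like sites (noise 5/15/25, gamma 1.0/1.5/2.0, FWHM
  1.0/2.5/4.0 mm), 30 scans/site — classification, MMD ratio, embeddings;
* null cohort, two identical profiles, 50 scans/site — accuracy must stay
  at chance and MMD must not beat a permutation null;
* single-parameter contrasts (noise 5 vs 20; FWHM 1 vs 4), 15 scans/site —
  importance recovery;
* resolution contrast, 1.0 mm/64³ vs 0.8 mm/80³ over the same field of
  view, 20 scans/site;
* the three-site cohort skull-stripped — σ_B features must be flagged
  missing while classification on the rest still succeeds.

On the smoothing-only contrast the HFR-must-rank-top expectation is not
met and is left as a documented failure: reconstruction smoothing rescales
the noise floor and the foreground-edge spectrum, so SNRF, GLCM
Correlation, CJV and the SNR features respond as strongly as HFR
(between-site Cohen's d of 20–65 for a dozen features at these
conditions), which puts the ranking in the saturation regime where top-3
membership is arbitrary.

## Numerical conventions

Population (N-divisor) variance throughout; log base 10 for all dB
quantities; reflect padding for the fixed 3×3 kernels; wavelet
decomposition depth fixed at one level; GLCM with 64 levels, distance 1,
four angles (all configurable); degenerate GLCM correlation := 1; EFC of
an all-zero slice, CV with μ_F = 0, CJV with μ_F = μ_B are missing; MMD
clipped at 0; median-heuristic bandwidth falls back to 1.0 if the median
pairwise distance is 0.
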