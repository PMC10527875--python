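"""Spatial-domain quality features of a masked slice.

Ten scalars: foreground intensity statistics (MEAN, RNG, VAR), coefficient
of variation (CV), noise-related ratios (PSNR, SNR1, SNR2, CNR), the
coefficient of joint variation (CJV), and the entropy focus criterion (EFC).

Conventions, applied throughout the package:

* all variances and standard deviations use the population (N-divisor) form;
* a feature whose precondition fails (empty region, zero denominator) is
  returned as ``nan``, the missing-value sentinel — typical for
  skull-stripped data where the background is identically zero;
* PSNR of a slice that equals its median-filtered reference (zero MSE) is
  ``+inf``, which aggregation treats as missing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from dsmri.preprocessing import (
    MaskedSlice,
    derive_seed,
    sample_patch_from_mask,
    sample_square_patch,
)

MISSING = float("nan")


def intensity_stats(masked: MaskedSlice) -> tuple[float, float, float]:
    """Foreground mean, range (max - min) and population variance."""
    fg = masked.foreground
    if fg.size == 0:
        return MISSING, MISSING, MISSING
    return float(fg.mean()), float(fg.max() - fg.min()), float(fg.var())


def coefficient_of_variation(masked: MaskedSlice) -> float:
    """CV = sigma_F / mu_F; missing when the foreground mean is zero."""
    fg = masked.foreground
    if fg.size == 0 or fg.mean() == 0:
        return MISSING
    return float(fg.std() / fg.mean())


def cjv(masked: MaskedSlice) -> float:
    """Coefficient of joint variation, (sigma_F + sigma_B) / |mu_F - mu_B|.

    Sensitive to shading, intensity non-uniformity and heavy motion.
    Missing when either region is empty or the two means coincide.
    """
    fg, bg = masked.foreground, masked.background
    if fg.size == 0 or bg.size == 0:
        return MISSING
    mu_f, mu_b = fg.mean(), bg.mean()
    if mu_f == mu_b:
        return MISSING
    return float((fg.std() + bg.std()) / abs(mu_f - mu_b))


def noise_metrics(
    masked: MaskedSlice, seed: int = 0, patch_side: int = 5, bg_guard: int = 8
) -> tuple[float, float, float, float]:
    """(psnr, snr1, snr2, cnr) of a slice.

    * SNR1 = sigma_F / sigma_B
    * SNR2 = mu_FP / sigma_B, with FP a seeded random foreground patch
    * CNR  = (mu_FP - mu_BP) / sigma_BP, with BP a background patch
    * PSNR = 10 log10(max(F)^2 / MSE) where the MSE is taken over foreground
      pixels between the slice and its 5x5 median-filtered version (the
      denoised reference).

    sigma_B and the background patch are taken from the *air region*: the
    background eroded by a ``bg_guard``-pixel band around the foreground, so
    that partial-volume edge pixels do not bleed into the noise estimate
    (standard practice for air-based noise estimation).  The default width
    of 8 pixels covers roughly 3 standard deviations of a 4 mm FWHM PSF at
    1 mm voxels, the strongest smoothing the features are expected to meet.

    Patch-dependent and sigma_B-dependent values are missing (nan) when the
    region is empty, no patch fits, or the denominator vanishes — the
    expected situation on skull-stripped data with an identically-zero
    background.
    """
    fg = masked.foreground
    if fg.size == 0:
        return MISSING, MISSING, MISSING, MISSING
    air_mask = masked.bg_mask
    if bg_guard > 0 and masked.fg_mask.any():
        air_mask = air_mask & ~ndimage.binary_dilation(
            masked.fg_mask, iterations=bg_guard
        )
    air = masked.image[air_mask]
    sigma_b = float(air.std()) if air.size else 0.0

    fp = sample_square_patch(masked, "foreground", patch_side, derive_seed(seed, "fp"))
    bp = sample_patch_from_mask(masked.image, air_mask, patch_side, derive_seed(seed, "bp"))

    snr1 = float(fg.std() / sigma_b) if sigma_b > 0 else MISSING
    snr2 = float(fp.values.mean() / sigma_b) if (fp is not None and sigma_b > 0) else MISSING

    cnr = MISSING
    if fp is not None and bp is not None:
        sigma_bp = float(bp.values.std())
        if sigma_bp > 0:
            cnr = float((fp.values.mean() - bp.values.mean()) / sigma_bp)

    reference = ndimage.median_filter(masked.image, size=patch_side, mode="reflect")
    mse = float(np.mean((masked.image[masked.fg_mask] - reference[masked.fg_mask]) ** 2))
    peak = float(np.max(np.abs(fg)))
    if mse == 0:
        psnr = math.inf
    elif peak == 0:
        psnr = MISSING
    else:
        psnr = float(10.0 * math.log10(peak**2 / mse))
    return psnr, snr1, snr2, cnr


def efc(masked: MaskedSlice) -> float:
    """Entropy focus criterion of the whole slice, normalized to [0, 1].

    With x_max = sqrt(sum x_j^2) over all H*W pixels, the Shannon entropy
    E = -sum (x_j / x_max) ln(x_j / x_max) is divided by its maximum
    sqrt(N) ln(sqrt(N)), attained by a uniform slice.  Blur and ghosting
    spread intensity over more pixels and push EFC toward 1; a single bright
    pixel gives 0.  Missing for an all-zero slice.
    """
    x = np.abs(np.asarray(masked.image, dtype=np.float64)).ravel()
    x_max = math.sqrt(float(np.sum(x * x)))
    if x_max == 0:
        return MISSING
    n = x.size
    if n < 2:
        return MISSING
    y = x / x_max
    nz = y > 0
    entropy = float(-np.sum(y[nz] * np.log(y[nz])))
    e_max = math.sqrt(n) * math.log(math.sqrt(n))
    return entropy / e_max
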