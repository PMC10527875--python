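"""Frequency-domain features from the 2-D FFT of a slice.

The spectrum is computed on the full rectangular slice with background
pixels zeroed, since the FFT needs a rectangular grid.  Three scalars:

* SNRF — decibel ratio of spectral power inside a central low-frequency
  disk (the signal) to the power outside it (the noise);
* LFR  — mean square-root amplitude spectrum after a 3x3 Gaussian low-pass;
* HFR  — mean square-root amplitude spectrum after a 3x3 Laplacian high-pass.

LFR and HFR scale as sqrt(k) under intensity scaling by k; that sensitivity
to scanner intensity scale is intentional.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, fftshift

from dsmri.preprocessing import MaskedSlice

#: 3x3 binomial low-pass kernel.
GAUSSIAN_KERNEL = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float64) / 16.0

#: 3x3 Laplacian high-pass kernel (zero-sum).
LAPLACIAN_KERNEL = np.array(
    [[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.float64
)


def _masked_image(masked: MaskedSlice) -> np.ndarray:
    return np.where(masked.fg_mask, masked.image, 0.0)


def _signal_mask(shape: tuple[int, int], radius_fraction: float) -> np.ndarray:
    """Boolean mask of spectrum bins within radius_fraction * r_max of DC.

    DC sits at (h//2, w//2) after fftshift.
    """
    h, w = shape
    rows = np.arange(h) - h // 2
    cols = np.arange(w) - w // 2
    radius = np.hypot(rows[:, None], cols[None, :])
    return radius <= radius_fraction * radius.max()


def snrf(masked: MaskedSlice, signal_radius_fraction: float = 0.25) -> float:
    """Frequency-domain SNR: 10 log10(P_signal / P_noise).

    P_signal is the squared-magnitude power within ``signal_radius_fraction``
    of the maximum radius from the centred DC bin; P_noise is the remainder.
    Returns +inf when no power falls outside the disk (e.g. constant slice).
    """
    if not 0 < signal_radius_fraction < 1:
        raise ValueError("signal_radius_fraction must lie in (0, 1)")
    spectrum = fftshift(fft2(_masked_image(masked)))
    power = np.abs(spectrum) ** 2
    inside = _signal_mask(power.shape, signal_radius_fraction)
    p_signal = float(power[inside].sum())
    p_noise = float(power[~inside].sum())
    if p_noise == 0:
        return math.inf
    if p_signal == 0:
        return -math.inf
    return float(10.0 * math.log10(p_signal / p_noise))


def _filtered_mean_root_amplitude(image: np.ndarray, kernel: np.ndarray) -> float:
    filtered = ndimage.convolve(image, kernel, mode="reflect")
    amplitude = np.abs(fft2(filtered))
    return float(np.mean(np.sqrt(amplitude)))


def lfr(masked: MaskedSlice) -> float:
    """Low-frequency response: Gaussian low-pass, FFT, mean root amplitude."""
    return _filtered_mean_root_amplitude(_masked_image(masked), GAUSSIAN_KERNEL)


def hfr(masked: MaskedSlice) -> float:
    """High-frequency response: Laplacian high-pass, FFT, mean root amplitude."""
    return _filtered_mean_root_amplitude(_masked_image(masked), LAPLACIAN_KERNEL)
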