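"""Wavelet-domain features from a single-level 2-D discrete wavelet transform.

The slice (background zeroed) is decomposed with an orthonormal wavelet —
first-order Coiflet by default, with Haar / Daubechies / Symlets / discrete
Meyer selectable — in periodization mode, so the transform is orthonormal
and Parseval's identity holds exactly.  All four subbands (approximation +
three details) are pooled into one flat coefficient sequence.

Three scalars summarise the coefficients:

* WCS — sparsity: mean magnitude of the "significant" coefficients, those
  with magnitude at or above the mean magnitude (ties count as significant);
* WQS — signed quality score: sum of magnitude * cos(phase); for real
  coefficients the phase is 0 or pi, so this is simply the coefficient sum;
* WCE — energy: mean absolute coefficient.

WCS >= WCE always (a mean over an above-threshold subset cannot fall below
the mean over all magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from dsmri.preprocessing import MaskedSlice

DEFAULT_WAVELET = "coif1"


@dataclass
class CoefficientSet:
    """Flat concatenation of the four one-level DWT subbands."""

    coefficients: np.ndarray
    wavelet_name: str

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).ravel()
        if self.coefficients.size == 0:
            raise ValueError("coefficient set must be non-empty")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def wavelet_decompose(
    masked: MaskedSlice, wavelet_name: str = DEFAULT_WAVELET
) -> CoefficientSet:
    """One-level 2-D DWT of the background-zeroed slice.

    Raises ValueError when the slice is smaller than the wavelet filter.
    """
    wavelet = pywt.Wavelet(wavelet_name)
    image = np.where(masked.fg_mask, masked.image, 0.0)
    if min(image.shape) < wavelet.dec_len:
        raise ValueError(
            f"slice of shape {image.shape} is too small for wavelet "
            f"{wavelet_name!r} (filter length {wavelet.dec_len})"
        )
    approx, details = pywt.dwt2(image, wavelet, mode="periodization")
    coeffs = np.concatenate([approx.ravel()] + [d.ravel() for d in details])
    return CoefficientSet(coefficients=coeffs, wavelet_name=wavelet_name)


def wcs(coeffs: CoefficientSet) -> float:
    """Wavelet coefficient sparsity: mean magnitude of above-mean coefficients."""
    magnitude = np.abs(coeffs.coefficients)
    threshold = magnitude.mean()
    significant = magnitude[magnitude >= threshold]
    return float(significant.mean())


def wqs(coeffs: CoefficientSet) -> float:
    """Wavelet quality score: sum of magnitude * cos(phase) = signed sum."""
    return float(coeffs.coefficients.sum())


def wce(coeffs: CoefficientSet) -> float:
    """Wavelet coefficient energy: mean absolute coefficient."""
    return float(np.abs(coeffs.coefficients).mean())
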