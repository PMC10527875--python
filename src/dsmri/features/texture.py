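"""GLCM texture features of the slice foreground.

Foreground intensities are linearly quantized to a fixed number of grey
levels (default 64); background pixels get a reserved ignore label that is
excluded from co-occurrence counting.  Co-occurrences are counted at
distance 1 along the four standard angles (0, 45, 90, 135 degrees),
symmetrized, normalized per angle and averaged into one matrix, from which
six Haralick-style properties are evaluated:

    contrast      = sum (i-j)^2 P(i,j)
    dissimilarity = sum |i-j|   P(i,j)
    ASM           = sum P(i,j)^2
    homogeneity   = sum P(i,j) / (1 + (i-j)^2)
    correlation   = sum (i-mu_i)(j-mu_j) P(i,j) / (sigma_i sigma_j)
    energy        = sqrt(ASM)

A degenerate matrix with zero marginal variance (constant image) has
correlation 1 by convention: a constant image is perfectly self-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from dsmri.preprocessing import MaskedSlice

#: Default (distance, angle) offsets: distance 1, four angles in radians.
DEFAULT_ANGLES: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class GreyCooccurrence:
    """A symmetric, normalized grey-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    distance: int
    angles: tuple[float, ...]

    def __post_init__(self) -> None:
        total = float(self.matrix.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM must sum to 1, got {total}")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("GLCM must be symmetric")


@dataclass
class TextureFeatureSet:
    contrast: float
    dissimilarity: float
    asm: float
    homogeneity: float
    correlation: float
    energy: float


def quantize_levels(masked: MaskedSlice, levels: int = 64) -> np.ndarray:
    """Quantize foreground intensities to ``{0, ..., levels-1}``.

    Linear rescale of the foreground [min, max] range; a constant foreground
    maps to level 0.  Background pixels receive the reserved ignore label
    ``levels``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    fg = masked.foreground
    if fg.size == 0:
        raise ValueError("foreground is empty")
    lo, hi = float(fg.min()), float(fg.max())
    out = np.full(masked.image.shape, levels, dtype=np.int32)
    if hi == lo:
        out[masked.fg_mask] = 0
    else:
        scaled = (masked.image[masked.fg_mask] - lo) / (hi - lo) * levels
        out[masked.fg_mask] = np.clip(scaled.astype(np.int32), 0, levels - 1)
    return out


def compute_glcm(
    quantized: np.ndarray,
    levels: int = 64,
    distance: int = 1,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
) -> GreyCooccurrence | None:
    """Count grey-level co-occurrences, excluding the ignore label.

    Per angle: count pairs at the (distance, angle) offset, add the
    transpose, normalize to sum 1.  The per-angle matrices are averaged.
    Returns None when no valid pixel pair exists at any offset.
    """
    counts = graycomatrix(
        quantized.astype(np.uint16),
        distances=[distance],
        angles=list(angles),
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )[:levels, :levels, 0, :].astype(np.float64)
    # drop angles with no valid (non-ignore) pair, then average normalized matrices
    totals = counts.sum(axis=(0, 1))
    valid = totals > 0
    if not valid.any():
        return None
    normalized = counts[:, :, valid] / totals[valid]
    matrix = normalized.mean(axis=2)
    return GreyCooccurrence(
        matrix=matrix, levels=levels, distance=distance, angles=tuple(angles)
    )


def glcm_properties(glcm: GreyCooccurrence) -> TextureFeatureSet:
    """Evaluate the six texture properties of a normalized symmetric GLCM."""
    p = glcm.matrix
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    diff = i - j
    contrast = float(np.sum(diff**2 * p))
    dissimilarity = float(np.sum(np.abs(diff) * p))
    asm = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + diff**2)))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        correlation = 1.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / denom)
    return TextureFeatureSet(
        contrast=contrast,
        dissimilarity=dissimilarity,
        asm=asm,
        homogeneity=homogeneity,
        correlation=correlation,
        energy=float(np.sqrt(asm)),
    )
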