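"""Per-slice foreground/background segmentation and seeded patch sampling.

The foreground detector is the substrate of every feature: Otsu threshold on
a lightly smoothed slice, 3x3 morphological closing, largest connected
component, hole filling.  Blank slices yield an empty foreground and are
flagged unusable rather than raising.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, footprint_rectangle


@dataclass
class MaskedSlice:
    """A 2-D slice with a foreground/background partition.

    ``fg_mask`` and ``bg_mask`` partition the slice: disjoint, jointly
    covering every pixel.  ``usable`` is False for blank slices with no
    detectable foreground.
    """

    image: np.ndarray
    fg_mask: np.ndarray
    bg_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.fg_mask.shape != self.image.shape or self.bg_mask.shape != self.image.shape:
            raise ValueError("masks must have the same shape as the image")
        if np.any(self.fg_mask & self.bg_mask):
            raise ValueError("foreground and background masks overlap")
        if not np.all(self.fg_mask | self.bg_mask):
            raise ValueError("masks must jointly cover the slice")

    @property
    def usable(self) -> bool:
        return bool(self.fg_mask.any())

    @property
    def fg_fraction(self) -> float:
        return float(self.fg_mask.mean())

    @property
    def foreground(self) -> np.ndarray:
        """Foreground intensities as a flat array."""
        return self.image[self.fg_mask]

    @property
    def background(self) -> np.ndarray:
        return self.image[self.bg_mask]


@dataclass
class Patch:
    """A square intensity patch lying entirely inside one region mask."""

    values: np.ndarray
    origin: tuple[int, int]


def full_mask_slice(image: np.ndarray) -> MaskedSlice:
    """Wrap an image with an all-foreground mask (convenience for tests/demos)."""
    image = np.asarray(image, dtype=np.float64)
    return MaskedSlice(
        image=image,
        fg_mask=np.ones(image.shape, dtype=bool),
        bg_mask=np.zeros(image.shape, dtype=bool),
    )


def detect_foreground(image: np.ndarray, smoothing_sigma: float = 1.0) -> MaskedSlice:
    """Segment a slice into anatomy-containing foreground and air background.

    Pipeline: Otsu threshold estimated on a lightly smoothed copy
    (``smoothing_sigma`` pixels) but applied to the original slice —
    smoothing stabilises the threshold under noise while thresholding the
    original keeps the boundary where the data put it — then 3x3 binary
    closing, largest connected component, hole filling.  The threshold is
    computed from the intensity histogram, so adding a constant offset to
    every pixel leaves the mask unchanged.

    Degenerate slices: a constant bright slice is all foreground; a constant
    non-positive slice (e.g. all zeros) has empty foreground and is flagged
    unusable via :attr:`MaskedSlice.usable`.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("slice intensities must be finite")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        # single-valued slice: bright => all foreground, zero/negative => blank
        fg = np.full(image.shape, hi > 0, dtype=bool)
        return MaskedSlice(image=image, fg_mask=fg, bg_mask=~fg)
    smoothed = gaussian(image, sigma=smoothing_sigma, preserve_range=True)
    threshold = threshold_otsu(smoothed)
    mask = image > threshold
    if mask.any():
        mask = closing(mask, footprint_rectangle((3, 3)))
        labels = label(mask, connectivity=2)
        if labels.max() > 0:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = labels == int(np.argmax(sizes))
        mask = ndimage.binary_fill_holes(mask)
    return MaskedSlice(image=image, fg_mask=mask, bg_mask=~mask)


def derive_seed(*parts: object) -> int:
    """Derive a stable 32-bit seed from arbitrary hashable parts.

    Used to key per-slice and per-volume random streams from
    (global seed, scan id, plane, slice index) so that results are
    reproducible and independent of processing order.
    """
    key = "\x1f".join(str(p) for p in parts)
    digest = hashlib.blake2s(key.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def sample_square_patch(
    masked: MaskedSlice, region: str, side: int = 5, seed: int = 0
) -> Patch | None:
    """Draw a seeded uniform random ``side`` x ``side`` patch inside a region.

    ``region`` is ``"foreground"`` or ``"background"``.  The patch is chosen
    uniformly among all windows whose every pixel lies inside the region
    mask; the same seed always returns the same patch.  Returns None when no
    admissible window exists (the caller records dependent features missing).
    """
    if region == "foreground":
        mask = masked.fg_mask
    elif region == "background":
        mask = masked.bg_mask
    else:
        raise ValueError(f"region must be 'foreground' or 'background', got {region!r}")
    return sample_patch_from_mask(masked.image, mask, side, seed)


def sample_patch_from_mask(
    image: np.ndarray, mask: np.ndarray, side: int, seed: int
) -> Patch | None:
    """Seeded uniform random side x side patch fully inside an arbitrary mask."""
    origins = admissible_origins(mask, side)
    if len(origins) == 0:
        return None
    rng = np.random.default_rng(seed)
    r, c = origins[rng.integers(len(origins))]
    return Patch(values=image[r : r + side, c : c + side].copy(), origin=(int(r), int(c)))


def admissible_origins(mask: np.ndarray, side: int) -> np.ndarray:
    """Top-left corners of all side x side windows fully inside ``mask``.

    Returns an (n, 2) integer array of (row, col) origins.
    """
    h, w = mask.shape
    if h < side or w < side:
        return np.empty((0, 2), dtype=int)
    # exact window sums via a padded integral image
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
    sums = (
        sat[side:, side:]
        - sat[:-side, side:]
        - sat[side:, :-side]
        + sat[:-side, :-side]
    )
    return np.argwhere(sums == side * side)
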