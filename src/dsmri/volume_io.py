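"""NIfTI volume I/O with a canonical axis convention.

All volumes are reoriented on load to the closest RAS-like axis order
(axis 0 = left-right, axis 1 = posterior-anterior, axis 2 = inferior-superior)
so that "axial", "coronal" and "sagittal" are well defined regardless of how
a file was stored.  Intensities are used exactly as stored: no rescaling or
normalization is applied, because scanner-dependent intensity scale is part
of the signal this package measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Admissible anatomical plane names and the canonical-volume axis each slices.
PLANE_AXES: dict[str, int] = {"sagittal": 0, "coronal": 1, "axial": 2}

PLANES: tuple[str, ...] = tuple(PLANE_AXES)


class VolumeFormatError(ValueError):
    """Raised for unreadable files or images that are not a 3-D volume."""


@dataclass
class Volume:
    """A 3-D structural MRI volume in canonical axis order.

    Parameters
    ----------
    data
        3-D floating-point intensity array, arbitrary units.
    spacing
        Voxel sizes in mm along the three canonical axes.
    scan_id
        Identifier of the scan; defaults to the source file stem.
    source_path
        Where the volume came from ("" for in-memory volumes).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    scan_id: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume data must have exactly 3 axes, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 8:
            raise VolumeFormatError(
                f"each volume axis must have length >= 8, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 volume (.nii or .nii.gz) and reorient it to canonical axes.

    NaN voxels are replaced by 0 with a logged warning.  4-D images (time
    series) are rejected.

    Raises
    ------
    VolumeFormatError
        If the file cannot be read as NIfTI or is not 3-D.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path} as a NIfTI file: {exc}") from exc
    if img.ndim != 3:
        raise VolumeFormatError(
            f"{path} is not a 3-D volume (shape {tuple(img.shape)}); "
            "4-D time series are not supported"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    scan_id = path.name
    for suffix in (".gz", ".nii"):
        if scan_id.endswith(suffix):
            scan_id = scan_id[: -len(suffix)]
    return Volume(data=data, spacing=spacing, scan_id=scan_id, source_path=str(path))


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal RAS affine built from its spacing."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def extract_slices(volume: Volume, plane: str) -> list[np.ndarray]:
    """Return all 2-D slices of ``volume`` along an anatomical plane.

    Slices are taken in voxel space (no resampling), in ascending index order
    along the canonical axis of the plane: axial = axis 2, coronal = axis 1,
    sagittal = axis 0.
    """
    if plane not in PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    axis = PLANE_AXES[plane]
    return [np.take(volume.data, i, axis=axis) for i in range(volume.data.shape[axis])]
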